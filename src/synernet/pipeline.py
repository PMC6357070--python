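"""End-to-end orchestration: validate a run configuration, execute the
marker, clinical and integration stages in order, and emit a
machine-readable run report whose counts are recomputed from the files
actually written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures, netio
from .clinical import clinical_results_table
from .datatypes import ClinicalTable, MarkerSet, PathwayLibrary, ValidationError
from .metabolome import fit_opls_da, pathway_analysis, q2_crossval, select_markers, vip_scores
from .network import assemble_ctp, compound_target_map, enrich_pathways, extract_subnetwork
from .synthetic import (
    ClinicalGenConfig,
    OmicsGenConfig,
    default_pathway_library,
    gen_clinical,
    gen_expression,
    gen_metabolites,
)
from .transcriptome import differential_genes


@dataclass
class RunConfig:
    """Single-document pipeline configuration (YAML-serializable)."""

    network: str = ""
    expression: str = ""
    metabolites: str = ""
    clinical: str = ""
    pathways: str = ""
    compounds: str = ""  # one compound id per line
    marker_phenotype: str = ""  # curated CSV: marker, phenotype
    target_pathway: str = ""  # curated CSV: target, pathway
    phenotype: str = fixtures.VASCULAR_PHENOTYPE
    out_dir: str = "synernet_out"
    seed: int = 0
    # stage toggles
    run_transcriptome: bool = True
    run_metabolome: bool = True
    run_clinical: bool = True
    run_integration: bool = True
    # thresholds
    fc_cut: float = 1.3
    p_cut: float = 0.05
    vip_cut: float = 1.0
    fdr: float = 0.01
    max_len: int = 3
    folds: int = 7
    n_orth: int = 1
    skew_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Issues preventing a run; empty list iff runnable."""
    issues: list[str] = []
    for name, lo, hi in (
        ("p_cut", 0, 1), ("fdr", 0, 1), ("fc_cut", 1, float("inf")),
        ("vip_cut", 0, float("inf")),
    ):
        v = getattr(config, name)
        if not (lo < v <= hi) and not (name == "vip_cut" and v == 0):
            issues.append(f"{name} out of range: {v}")
    if config.max_len < 1:
        issues.append(f"max_len out of range: {config.max_len}")
    if config.folds < 2:
        issues.append(f"folds out of range: {config.folds}")
    stage_inputs = {
        "run_transcriptome": ["expression"],
        "run_metabolome": ["metabolites", "pathways"],
        "run_clinical": ["clinical"],
        "run_integration": ["network", "compounds", "marker_phenotype"],
    }
    for toggle, paths in stage_inputs.items():
        if getattr(config, toggle):
            for attr in paths:
                p = getattr(config, attr)
                if not p:
                    issues.append(f"{attr} path required for {toggle}")
                elif not Path(p).exists():
                    issues.append(f"{attr} path does not exist: {p}")
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in order; return (and write) the run report.

    Stage order: transcriptome and metabolome markers, clinical comparison,
    network integration. A stage failure marks the stage failed and skips
    dependent stages. Rerunning with identical config + seed reproduces
    identical outputs.
    """
    issues = validate_config(config)
    if issues:
        raise ValidationError("invalid config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "status": "ok", "seed": config.seed}
    markers = MarkerSet()

    if config.run_transcriptome:
        try:
            expr = netio.read_expression(config.expression)
            de = differential_genes(expr, fc_cut=config.fc_cut, p_cut=config.p_cut)
            de.to_csv(out / "de.csv", index=False)
            for _, row in de[de["passes"]].iterrows():
                markers.add(str(row["gene"]), "transcriptome",
                            "up" if row["log2fc"] >= 0 else "down")
            written = pd.read_csv(out / "de.csv")
            report["stages"]["transcriptome"] = {
                "status": "ok",
                "params": {"fc_cut": config.fc_cut, "p_cut": config.p_cut},
                "n_genes": int(len(written)),
                "n_passing": int(written["passes"].sum()),
            }
        except Exception as e:  # noqa: BLE001 - report, don't crash the run
            report["stages"]["transcriptome"] = {"status": "failed", "error": str(e)}
            report["status"] = "failed"

    if config.run_metabolome:
        try:
            table = netio.read_metabolites(config.metabolites)
            library = netio.read_gmt(config.pathways)
            model = fit_opls_da(table, n_orth=config.n_orth)
            q2 = q2_crossval(table, n_orth=config.n_orth, folds=config.folds,
                             seed=config.seed)
            vips = vip_scores(model, table)
            mset, detail = select_markers(model, table, vip_cut=config.vip_cut,
                                          p_cut=config.p_cut)
            universe = set(table.values.index)
            pathway_table = pathway_analysis(mset, library, universe)
            pd.DataFrame({"sample": table.values.columns, "t": model.t_}).to_csv(
                out / "opls_scores.csv", index=False)
            vips.to_csv(out / "vip.csv")
            detail.to_csv(out / "metabolite_markers.csv", index=False)
            pathway_table.to_csv(out / "metabolite_pathways.csv", index=False)
            for m in mset:
                markers.add(m.id, m.source, m.direction, m.tier)
            written = pd.read_csv(out / "metabolite_markers.csv")
            report["stages"]["metabolome"] = {
                "status": "ok",
                "params": {"vip_cut": config.vip_cut, "p_cut": config.p_cut,
                           "n_orth": config.n_orth, "folds": config.folds},
                "n_metabolites": int(len(written)),
                "n_discriminant": int((written["tier"] != "none").sum()),
                "n_significant": int((written["tier"] == "significant").sum()),
                "r2y": float(model.r2y_),
                "q2": float(q2),
            }
        except Exception as e:  # noqa: BLE001
            report["stages"]["metabolome"] = {"status": "failed", "error": str(e)}
            report["status"] = "failed"

    if config.run_clinical:
        try:
            table = ClinicalTable.read_csv(config.clinical)
            results = clinical_results_table(table, skew_threshold=config.skew_threshold)
            results.to_csv(out / "clinical_results.csv", index=False)
            sig = results[results["p_group"] < config.p_cut]
            for outcome in sig["outcome"].unique():
                sub = sig[sig["outcome"] == outcome]
                direction = "down" if sub["ls_mean"].iloc[-1] < sub["ls_mean"].iloc[0] else "up"
                markers.add(str(outcome), "clinical", direction)
            written = pd.read_csv(out / "clinical_results.csv")
            report["stages"]["clinical"] = {
                "status": "ok",
                "params": {"skew_threshold": config.skew_threshold},
                "n_outcomes": int(written["outcome"].nunique()),
                "n_significant_outcomes": int(
                    written[written["p_group"] < config.p_cut]["outcome"].nunique()),
            }
        except Exception as e:  # noqa: BLE001
            report["stages"]["clinical"] = {"status": "failed", "error": str(e)}
            report["status"] = "failed"

    markers.to_frame().to_csv(out / "markers.csv", index=False)

    if config.run_integration:
        if report["status"] == "failed":
            report["stages"]["integration"] = {"status": "skipped",
                                               "reason": "an earlier stage failed"}
        else:
            try:
                report["stages"]["integration"] = _integrate(config, markers, out)
            except Exception as e:  # noqa: BLE001
                report["stages"]["integration"] = {"status": "failed", "error": str(e)}
                report["status"] = "failed"

    with (out / "run_report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _integrate(config: RunConfig, markers: MarkerSet, out: Path) -> dict:
    net = netio.read_network(config.network)
    compounds = {
        line.strip() for line in Path(config.compounds).read_text().splitlines()
        if line.strip()
    }
    curated = pd.read_csv(config.marker_phenotype)
    sink_ids = markers.ids() | set(curated["marker"].astype(str))
    sub = extract_subnetwork(net, compounds, sink_ids, config.phenotype,
                             max_len=config.max_len)
    ct = compound_target_map(sub)
    gm = {n for n in sub.graph.nodes if net.kind_of(n) in ("protein", "metabolite")}
    universe = net.nodes_of_kind("protein") | net.nodes_of_kind("metabolite")
    enrichment = None
    library = None
    if config.pathways:
        library = netio.read_gmt(config.pathways)
        usable = {n: mem for n, mem in library.members.items() if mem & universe}
        if usable:
            enrichment = enrich_pathways(
                gm & universe, PathwayLibrary(usable), universe, fdr=config.fdr)
            enrichment.to_csv(out / "enrichment.csv", index=False)
    curated_links = None
    if config.target_pathway:
        tp = pd.read_csv(config.target_pathway)
        curated_links = list(zip(tp["target"].astype(str), tp["pathway"].astype(str)))
    ctp = assemble_ctp(sub, enrichment=enrichment, curated_links=curated_links,
                       library=library)
    from .datatypes import HeteroNetwork
    export = HeteroNetwork(ctp.graph.copy())
    netio.write_network(export, out / "ctp.sif", fmt="sif")
    netio.write_network(export, out / "ctp.graphml", fmt="graphml")
    netio.write_node_attributes(export, out / "ctp_nodes.csv")
    edges = pd.DataFrame(
        [(u, v, d.get("relation", "")) for u, v, d in ctp.graph.edges(data=True)],
        columns=["source", "target", "relation"],
    ).sort_values(["source", "target"]).reset_index(drop=True)
    edges.to_csv(out / "ctp_edges.csv", index=False)
    nodes_written = pd.read_csv(out / "ctp_nodes.csv")
    edges_written = pd.read_csv(out / "ctp_edges.csv")
    return {
        "status": "ok",
        "params": {"fdr": config.fdr, "max_len": config.max_len,
                   "phenotype": config.phenotype},
        "n_compounds": int((nodes_written["kind"] == "compound").sum()),
        "n_targets": int(nodes_written["kind"].isin(["protein", "metabolite"]).sum()),
        "n_pathways": int((nodes_written["kind"] == "pathway").sum()),
        "n_compound_target_edges": int((edges_written["relation"] == "targets").sum()),
        "n_edges": int(len(edges_written)),
        "per_compound_targets": {c: len(ts) for c, ts in sorted(ct.items())},
    }


def materialize_demo_inputs(out_dir, seed: int = 42) -> RunConfig:
    """Write the synthetic bundle + curated fixture files and a run config.

    Expression: 1000 genes, 50 planted at 2-fold; metabolites: default
    panel with 8 strongly shifted; clinical: three arms with a planted
    high-arm blood-pressure/stiffness reduction; network: the curated
    vascular fixture embedded among decoys.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = [f"g{i+1:04d}" for i in range(1000)]
    expr_cfg = OmicsGenConfig(
        n_genes=1000, n_samples_per_group=10,
        planted_de_genes=set(genes[:50]), planted_fold_change=2.0,
        noise_sd=0.4, seed=seed,
    )
    netio.write_expression(gen_expression(expr_cfg), out / "expression.csv")

    shifts = {m: 1.8 for m in (
        "cis-aconitate", "malonate", "N-acetylglycine", "O-acetylcholine",
        "succinate", "urea", "valproate", "2-oxoglutarate",
    )}
    met_cfg = OmicsGenConfig(
        n_samples_per_group=12, planted_shift_metabolites=shifts,
        noise_sd=0.4, seed=seed + 1,
    )
    netio.write_metabolites(gen_metabolites(met_cfg), out / "metabolites.csv")

    clin_cfg = ClinicalGenConfig(
        n_per_arm=21,
        treatment_effect={("high", "baPWV"): -5.0, ("low", "baPWV"): -2.0,
                          ("high", "SBP"): -4.0},
        within_subject_sd=20.0, seed=seed + 2,
    )
    gen_clinical(clin_cfg).to_csv(out / "clinical.csv")

    net = fixtures.vascular_fixture_network()
    netio.write_network(net, out / "network.tsv", fmt="tsv")
    fx = fixtures.vascular_fixture()
    compounds = sorted(net.nodes_of_kind("compound"))
    (out / "compounds.txt").write_text("\n".join(compounds) + "\n")
    fixtures.vascular_marker_phenotype_table().to_csv(
        out / "marker_phenotype.csv", index=False)
    pd.DataFrame(fx.target_pathway_edges, columns=["target", "pathway"]).to_csv(
        out / "target_pathway.csv", index=False)
    netio.write_gmt(default_pathway_library(), out / "pathways.gmt")

    config = RunConfig(
        network=str(out / "network.tsv"),
        expression=str(out / "expression.csv"),
        metabolites=str(out / "metabolites.csv"),
        clinical=str(out / "clinical.csv"),
        pathways=str(out / "pathways.gmt"),
        compounds=str(out / "compounds.txt"),
        marker_phenotype=str(out / "marker_phenotype.csv"),
        target_pathway=str(out / "target_pathway.csv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    config.to_yaml(out / "run.yaml")
    return config


def run_demo(out_dir, seed: int = 42) -> dict:
    """Materialize the synthetic bundle and run the full pipeline on it."""
    config = materialize_demo_inputs(out_dir, seed=seed)
    return run_pipeline(config)
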