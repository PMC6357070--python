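"""Seeded generators for every pipeline input.

Each generator plants known structure — connected compound-target-phenotype
paths, differentially expressed genes at a fixed fold change, group-shifted
metabolite concentrations, per-arm treatment effects on clinical outcomes —
so downstream stages can be validated by parameter recovery. All randomness
flows through ``numpy.random.default_rng(seed)``; identical config + seed
gives identical output.

Distributional conventions (the trial data are not deposited, so these are
field-standard choices, not reconstructions): expression noise is Gaussian
on the log2 scale (lognormal on the linear scale, matching fold-change
semantics), metabolite concentrations are lognormal (positive, multiplicative
group shifts), and clinical outcomes are Gaussian baselines with additive
follow-up noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    HeteroNetwork,
    MetaboliteTable,
    ValidationError,
)

#: Urinary NMR metabolite panel used by default; the first eight are the
#: canonical discriminant set for this intervention.
DEFAULT_METABOLITES: tuple[str, ...] = (
    "cis-aconitate",
    "malonate",
    "N-acetylglycine",
    "O-acetylcholine",
    "succinate",
    "urea",
    "valproate",
    "2-oxoglutarate",
    "citrate",
    "creatinine",
    "hippurate",
    "glycine",
    "alanine",
    "taurine",
    "betaine",
    "dimethylamine",
    "trimethylamine N-oxide",
    "formate",
    "lactate",
    "acetate",
    "pyruvate",
    "fumarate",
    "glutamine",
    "histidine",
    "threonine",
    "serine",
    "proline",
    "arginine",
    "choline",
    "creatine",
)


@dataclass
class NetworkGenConfig:
    """Configuration for the random heterogeneous-network generator.

    ``planted_paths`` are (compound, target, phenotype) triples guaranteed
    to exist as directed compound->target->phenotype routes on top of
    density-``edge_density`` random background edges.
    """

    n_compounds: int = 10
    n_proteins: int = 30
    n_metabolites: int = 10
    n_pathways: int = 6
    n_phenotypes: int = 2
    edge_density: float = 0.05
    planted_paths: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0

    def node_ids(self) -> dict[str, list[str]]:
        return {
            "compound": [f"C{i+1}" for i in range(self.n_compounds)],
            "protein": [f"P{i+1}" for i in range(self.n_proteins)],
            "metabolite": [f"M{i+1}" for i in range(self.n_metabolites)],
            "pathway": [f"W{i+1}" for i in range(self.n_pathways)],
            "phenotype": [f"Ph{i+1}" for i in range(self.n_phenotypes)],
        }

    def validate(self) -> None:
        for name in ("n_compounds", "n_proteins", "n_metabolites", "n_pathways", "n_phenotypes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0 <= self.edge_density <= 1):
            raise ValidationError("edge_density must be in [0, 1]")
        ids = self.node_ids()
        compounds = set(ids["compound"])
        mids = set(ids["protein"]) | set(ids["metabolite"])
        phenos = set(ids["phenotype"])
        for c, t, ph in self.planted_paths:
            if c not in compounds:
                raise ValidationError(f"planted path compound {c!r} not among declared ids")
            if t not in mids:
                raise ValidationError(f"planted path target {t!r} not among declared ids")
            if ph not in phenos:
                raise ValidationError(f"planted path phenotype {ph!r} not among declared ids")


@dataclass
class OmicsGenConfig:
    """Configuration shared by the expression and metabolite generators."""

    n_genes: int = 1000
    n_samples_per_group: int = 10
    planted_de_genes: set[str] = field(default_factory=set)
    planted_fold_change: float = 2.0
    noise_sd: float = 0.4
    metabolite_names: tuple[str, ...] = DEFAULT_METABOLITES
    planted_shift_metabolites: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"g{i+1:04d}" for i in range(self.n_genes)]

    def validate(self, for_metabolites: bool = False) -> None:
        if self.n_samples_per_group < 2:
            raise ValidationError("n_samples_per_group must be >= 2")
        if self.planted_fold_change <= 1:
            raise ValidationError("planted_fold_change must be > 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if for_metabolites:
            if not self.metabolite_names:
                raise ValidationError("metabolite_names must be non-empty")
            for name, ratio in self.planted_shift_metabolites.items():
                if ratio <= 0:
                    raise ValidationError(f"shift ratio for {name!r} must be > 0")
                if name not in self.metabolite_names:
                    raise ValidationError(f"shifted metabolite {name!r} not in metabolite_names")
        else:
            unknown = self.planted_de_genes - set(self.gene_ids())
            if unknown:
                raise ValidationError(f"planted_de_genes not among generated ids: {sorted(unknown)[:5]}")


@dataclass
class ClinicalGenConfig:
    """Three-arm (placebo / low / high) clinical-trial generator settings.

    ``treatment_effect`` maps (arm, outcome) to the planted mean relative
    change in percent; ``within_subject_sd`` is the additive SD of the
    follow-up measurement in outcome units.
    """

    n_per_arm: int = 20
    arms: tuple[str, ...] = ("placebo", "low", "high")
    baseline: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"baPWV": (1400.0, 120.0), "SBP": (125.0, 10.0)}
    )
    treatment_effect: Mapping[tuple[str, str], float] = field(default_factory=dict)
    within_subject_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ValidationError("n_per_arm must be >= 2")
        if len(self.arms) < 2:
            raise ValidationError("need at least 2 arms")
        for outcome, (_, sd) in self.baseline.items():
            if sd <= 0:
                raise ValidationError(f"baseline_sd for {outcome!r} must be > 0")
        for (arm, outcome) in self.treatment_effect:
            if arm not in self.arms:
                raise ValidationError(f"treatment_effect arm {arm!r} not declared")
            if outcome not in self.baseline:
                raise ValidationError(f"treatment_effect outcome {outcome!r} not declared")


# kind pairs eligible for random background edges (directed)
_ELIGIBLE = (
    ("compound", "protein"),
    ("compound", "metabolite"),
    ("protein", "protein"),
    ("protein", "metabolite"),
    ("metabolite", "protein"),
    ("protein", "pathway"),
    ("metabolite", "pathway"),
    ("protein", "phenotype"),
    ("metabolite", "phenotype"),
)


def gen_hetero_network(config: NetworkGenConfig) -> HeteroNetwork:
    """Random typed directed network with guaranteed planted routes.

    Every (compound, target, phenotype) triple in ``config.planted_paths``
    is wired as two directed edges compound->target and target->phenotype,
    so the phenotype is always reachable from the compound. Background edges
    are added independently with probability ``edge_density`` per eligible
    ordered node pair.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = config.node_ids()
    net = HeteroNetwork()
    for kind, nodes in ids.items():
        for n in nodes:
            net.add_node(n, kind)
    for c, t, ph in config.planted_paths:
        net.add_edge(c, t, relation="targets", provenance="curated")
        net.add_edge(t, ph, relation="associated_with", provenance="curated")
    if config.edge_density > 0:
        for src_kind, dst_kind in _ELIGIBLE:
            for u in ids[src_kind]:
                draws = rng.random(len(ids[dst_kind]))
                for v, r in zip(ids[dst_kind], draws):
                    if u != v and r < config.edge_density:
                        if not net.graph.has_edge(u, v):
                            net.add_edge(u, v, relation="association", provenance="inferred")
    return net


def gen_expression(config: OmicsGenConfig) -> ExpressionMatrix:
    """Two-group expression matrix with planted fold changes.

    Per-gene log2 baseline is uniform on [6, 12); samples add N(0, noise_sd)
    log2 noise; planted genes get +log2(fold change) in the treatment group.
    Expected linear-scale group ratio is the planted fold change for planted
    genes and 1 elsewhere (the lognormal noise factor cancels in the ratio
    of expectations).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    n = config.n_samples_per_group
    base = rng.uniform(6.0, 12.0, size=len(genes))
    noise = rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * n))
    log2fc = np.log2(config.planted_fold_change)
    shift = np.zeros((len(genes), 2 * n))
    planted_idx = [i for i, g in enumerate(genes) if g in config.planted_de_genes]
    shift[planted_idx, n:] = log2fc
    values = np.exp2(base[:, None] + noise + shift)
    samples = [f"ctrl_{i+1}" for i in range(n)] + [f"trt_{i+1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["treatment"] * n, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


def gen_metabolites(config: OmicsGenConfig) -> MetaboliteTable:
    """Two-group lognormal metabolite concentration table with planted shifts.

    Group-2 concentrations of metabolites in ``planted_shift_metabolites``
    are multiplied by the stated ratio; all concentrations are strictly
    positive.
    """
    config.validate(for_metabolites=True)
    rng = np.random.default_rng(config.seed)
    names = list(config.metabolite_names)
    n = config.n_samples_per_group
    base = rng.uniform(0.0, 3.0, size=len(names))  # natural-log median concentration
    noise = rng.normal(0.0, config.noise_sd, size=(len(names), 2 * n))
    ratios = np.array([config.planted_shift_metabolites.get(m, 1.0) for m in names])
    shift = np.zeros((len(names), 2 * n))
    shift[:, n:] = np.log(ratios)[:, None]
    values = np.exp(base[:, None] + noise + shift)
    samples = [f"P_{i+1}" for i in range(n)] + [f"H_{i+1}" for i in range(n)]
    groups = pd.Series(["placebo"] * n + ["treatment"] * n, index=samples)
    return MetaboliteTable(pd.DataFrame(values, index=names, columns=samples), groups)


def gen_clinical(config: ClinicalGenConfig) -> ClinicalTable:
    """Per-subject baseline and week-4 values with planted arm effects.

    week4 = baseline x (1 + effect/100) + N(0, within_subject_sd); since the
    additive noise has mean zero and is independent of the baseline, the
    expected relative change in each arm equals the planted effect.

    Random draws are keyed to arm *position*, so relabelling arms permutes
    labels without changing the underlying values.
    """
    config.validate()
    rows = []
    for ai, arm in enumerate(config.arms):
        for oi, (outcome, (mean, sd)) in enumerate(sorted(config.baseline.items())):
            # child stream per (arm position, outcome position) for label symmetry
            rng = np.random.default_rng([config.seed, ai, oi])
            effect = config.treatment_effect.get((arm, outcome), 0.0)
            baseline = rng.normal(mean, sd, size=config.n_per_arm)
            week4 = baseline * (1.0 + effect / 100.0) + rng.normal(
                0.0, config.within_subject_sd, size=config.n_per_arm
            )
            for i in range(config.n_per_arm):
                rows.append((f"{arm}_{i+1:03d}", arm, outcome, baseline[i], week4[i]))
    return ClinicalTable(
        pd.DataFrame(rows, columns=["subject", "arm", "outcome", "baseline", "week4"])
    )


def default_pathway_library() -> dict[str, set[str]]:
    """Metabolite pathway library matching the default panel.

    Six urinary pathways whose memberships overlap the default metabolite
    names; suitable for exercising over-representation analysis on
    generator output.
    """
    return {
        "TCA cycle": {"succinate", "citrate", "2-oxoglutarate", "fumarate", "pyruvate",
                      "cis-aconitate", "malonate"},
        "alanine, aspartate and glutamate metabolism": {"alanine", "glutamine",
                                                        "2-oxoglutarate", "succinate",
                                                        "fumarate", "pyruvate"},
        "arginine and proline metabolism": {"arginine", "proline", "urea", "creatine",
                                            "glutamine", "pyruvate"},
        "D-glutamine and D-glutamate metabolism": {"glutamine", "2-oxoglutarate"},
        "glycine, serine and threonine metabolism": {"glycine", "serine", "threonine",
                                                     "betaine", "creatine", "choline",
                                                     "N-acetylglycine", "pyruvate"},
        "propanoate metabolism": {"lactate", "acetate", "succinate", "valproate",
                                  "malonate"},
    }
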