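"""Curated vascular subnetwork fixture.

The six bioactives of Sanghuang (*Phellinus baumii*) and Danshen
(*Salvia miltiorrhiza*) that reach vascular-dilation markers, their 15
molecular targets (14 proteins plus the metabolite succinate), and the six
metabolic pathways those targets belong to. The compound-target lists and
target-pathway links are the curated vascular subnetwork content; the gene
symbol NOS3 (endothelial nitric-oxide synthase) appears in some printed
target lists in a corrupted form ("NO53") and is normalized here.

Also provides a full heterogeneous demo network embedding this subnetwork
among decoy compounds and proteins, so that shortest-path extraction has
something to discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import HeteroNetwork

# Compound -> target adjacency of the vascular subnetwork.
# Targets are direct: 9 + 8 + 8 + 5 + 5 + 4 = 39 edges over 15 distinct targets.
_COMPOUND_TARGETS: dict[str, tuple[str, ...]] = {
    "ellagic acid": (
        "ARG2", "CALR", "COX2", "CYP1A1", "JUN", "NOS3", "PLA2G2A", "SUCLG1", "succinate",
    ),
    "caffeic acid": (
        "ALOX15", "ALOX5", "COX2", "CYP2E1", "EDN1", "NOS3", "SUCLG1", "succinate",
    ),
    "protocatechuic acid": (
        "ALDH7A1", "COX1", "COX2", "CYP1A1", "CYP2E1", "NOS3", "SUCLG1", "succinate",
    ),
    "cryptotanshinone": ("ALDH7A1", "CYP1A1", "NOS3", "SUCLG1", "succinate"),
    "tanshinone I": ("ALDH7A1", "CYP1A1", "NOS3", "SUCLG1", "succinate"),
    "tanshinone IIA": ("EDN1", "NOS3", "SUCLG1", "succinate"),
}

# Target -> pathway curated links (Fig-style component-target-pathway layer).
_TARGET_PATHWAYS: dict[str, tuple[str, ...]] = {
    "NOS3": ("arginine and proline metabolism",),
    "SUCLG1": (
        "TCA cycle",
        "alanine, aspartate and glutamate metabolism",
        "D-glutamine and D-glutamate metabolism",
    ),
    "succinate": (
        "TCA cycle",
        "alanine, aspartate and glutamate metabolism",
        "D-glutamine and D-glutamate metabolism",
    ),
    "ALDH7A1": (
        "glycine, serine and threonine metabolism",
        "propanoate metabolism",
    ),
}

_METABOLITE_TARGETS = frozenset({"succinate"})

# Synthetic decoy constituents standing in for the remaining signature
# bioactives whose identities are not enumerated in the curated lists.
# They reach only decoy proteins, never a vascular marker.
_DECOY_COMPOUNDS = (
    "salvianolic acid A",
    "salvianolic acid B",
    "danshensu",
    "hispidin",
    "davallialactone",
    "hypholomine B",
)
_DECOY_PROTEINS = ("TP53", "EGFR", "TNF", "IL6", "AKT1", "MAPK1")

VASCULAR_PHENOTYPE = "vascular endothelial dilation"


@dataclass
class VascularFixture:
    """The printed vascular component-target(-pathway) subnetwork.

    Attributes
    ----------
    compound_target_edges : list of (compound, target) pairs, 39 total
    target_pathway_edges : curated (target, pathway) pairs
    node_kinds : id -> kind for every fixture node
    """

    compound_target_edges: list[tuple[str, str]] = field(default_factory=list)
    target_pathway_edges: list[tuple[str, str]] = field(default_factory=list)
    node_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def compounds(self) -> list[str]:
        return sorted({c for c, _ in self.compound_target_edges})

    @property
    def targets(self) -> list[str]:
        return sorted({t for _, t in self.compound_target_edges})

    @property
    def pathways(self) -> list[str]:
        return sorted({p for _, p in self.target_pathway_edges})

    def targets_of(self, compound: str) -> set[str]:
        return {t for c, t in self.compound_target_edges if c == compound}


def vascular_fixture() -> VascularFixture:
    """Build the curated vascular subnetwork fixture.

    Six compounds, 15 targets (14 proteins + succinate), six pathways;
    per-compound target counts 9/8/8/5/5/4.
    """
    ct = [(c, t) for c, targets in _COMPOUND_TARGETS.items() for t in targets]
    tp = [(t, p) for t, paths in _TARGET_PATHWAYS.items() for p in paths]
    kinds: dict[str, str] = {}
    for c in _COMPOUND_TARGETS:
        kinds[c] = "compound"
    for _, t in ct:
        kinds[t] = "metabolite" if t in _METABOLITE_TARGETS else "protein"
    for _, p in tp:
        kinds[p] = "pathway"
    return VascularFixture(ct, tp, kinds)


def vascular_fixture_network(include_decoys: bool = True) -> HeteroNetwork:
    """Heterogeneous demo network embedding the vascular fixture.

    Contains the six vascular compounds wired to their printed targets, each
    target wired to the vascular-dilation phenotype node (the curated
    marker-phenotype layer), plus — when ``include_decoys`` — six decoy
    compounds wired only to decoy proteins that never reach the phenotype.
    """
    fx = vascular_fixture()
    net = HeteroNetwork()
    net.add_node(VASCULAR_PHENOTYPE, "phenotype", context="vascular")
    for node, kind in fx.node_kinds.items():
        if kind != "pathway":
            net.add_node(node, kind, context="vascular")
    for c, t in fx.compound_target_edges:
        net.add_edge(c, t, relation="targets", provenance="curated")
    for t in fx.targets:
        net.add_edge(t, VASCULAR_PHENOTYPE, relation="associated_with", provenance="curated")
    if include_decoys:
        for c in _DECOY_COMPOUNDS:
            net.add_node(c, "compound")
        for p in _DECOY_PROTEINS:
            net.add_node(p, "protein")
        for i, c in enumerate(_DECOY_COMPOUNDS):
            net.add_edge(c, _DECOY_PROTEINS[i % len(_DECOY_PROTEINS)], relation="targets",
                         provenance="curated")
            net.add_edge(c, _DECOY_PROTEINS[(i + 1) % len(_DECOY_PROTEINS)], relation="targets",
                         provenance="curated")
    return net


def vascular_marker_phenotype_table() -> pd.DataFrame:
    """Curated marker -> phenotype table for the fixture (read, never inferred)."""
    fx = vascular_fixture()
    return pd.DataFrame(
        [(t, VASCULAR_PHENOTYPE) for t in fx.targets],
        columns=["marker", "phenotype"],
    )


def baseline_contingency_tables() -> dict[str, pd.DataFrame]:
    """Categorical baseline characteristics of the trial arms as count tables.

    Rows are arms (placebo, low, high); columns are category levels. The
    alcohol-consumption table reproduces the published between-arm p-value
    under an uncorrected Pearson chi-square; the gender table is known not
    to (the original analysis likely used an exact test on that sparse
    table) and is provided for completeness only.
    """
    alcohol = pd.DataFrame(
        [[14, 7], [13, 10], [14, 6]],
        index=["placebo", "low", "high"],
        columns=["yes", "no"],
    )
    gender = pd.DataFrame(
        [[19, 2], [21, 2], [19, 1]],
        index=["placebo", "low", "high"],
        columns=["male", "female"],
    )
    return {"alcohol": alcohol, "gender": gender}
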