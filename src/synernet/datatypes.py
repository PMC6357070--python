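"""Shared in-memory containers for the pipeline stages.

Tabular data live in pandas objects; the heterogeneous network wraps a
networkx DiGraph with a closed set of node kinds. Containers validate on
construction so downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

NODE_KINDS = frozenset({"compound", "protein", "metabolite", "pathway", "phenotype"})

#: Cytoscape shape hints per Fig-style conventions: proteins round, metabolites triangle.
SHAPE_HINTS = {
    "protein": "round",
    "metabolite": "triangle",
    "compound": "diamond",
    "pathway": "rectangle",
    "phenotype": "hexagon",
}


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Two-group gene-expression matrix, linear scale, strictly positive.

    Parameters
    ----------
    values : DataFrame, genes x samples
    groups : Series indexed by sample id giving one of exactly two group labels
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if list(self.values.columns) != list(self.groups.index):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValidationError("every sample needs a group label")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values.to_numpy() <= 0).any():
            raise ValidationError("expression values must be strictly positive")
        counts = self.groups.value_counts()
        if len(counts) != 2:
            raise ValidationError(f"expected exactly 2 groups, got {len(counts)}")
        if (counts < 2).any():
            raise ValidationError("each group needs at least 2 samples")

    @property
    def group_labels(self) -> tuple[str, str]:
        """The two labels, reference group first (sorted for determinism)."""
        return tuple(sorted(self.groups.unique()))  # type: ignore[return-value]

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Columns of group 1 and group 2, in label-sorted order."""
        g1, g2 = self.group_labels
        return (
            self.values.loc[:, self.groups[self.groups == g1].index],
            self.values.loc[:, self.groups[self.groups == g2].index],
        )


@dataclass
class MetaboliteTable:
    """Quantified metabolite concentrations (metabolites x samples), two groups."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if list(self.values.columns) != list(self.groups.index):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValidationError("every sample needs a group label")
        if self.values.isna().any().any():
            raise ValidationError("metabolite table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("concentrations must be non-negative")
        counts = self.groups.value_counts()
        if len(counts) != 2:
            raise ValidationError(f"expected exactly 2 groups, got {len(counts)}")
        if (counts < 3).any():
            raise ValidationError("each group needs at least 3 samples for model fitting")

    @property
    def group_labels(self) -> tuple[str, str]:
        return tuple(sorted(self.groups.unique()))  # type: ignore[return-value]

    def y_pm1(self) -> np.ndarray:
        """Class membership encoded -1 (first sorted label) / +1 (second)."""
        g1, _ = self.group_labels
        return np.where(self.groups.to_numpy() == g1, -1.0, 1.0)


class ClinicalTable:
    """Per-subject baseline and week-4 outcome values by arm.

    Long format: one row per subject x outcome with columns
    ``subject``, ``arm``, ``outcome``, ``baseline``, ``week4``.
    """

    REQUIRED = ("subject", "arm", "outcome", "baseline", "week4")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if data.duplicated(subset=["subject", "outcome"]).any():
            raise ValidationError("one row per subject x outcome required")
        vals = data[["baseline", "week4"]].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("baseline/week4 values must be finite")
        self.data = data.reset_index(drop=True)

    @property
    def arms(self) -> list[str]:
        return sorted(self.data["arm"].unique())

    @property
    def outcomes(self) -> list[str]:
        return sorted(self.data["outcome"].unique())

    def outcome_frame(self, outcome: str) -> pd.DataFrame:
        sub = self.data[self.data["outcome"] == outcome]
        if sub.empty:
            raise KeyError(f"outcome {outcome!r} not present")
        return sub.copy()

    @classmethod
    def read_csv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class Marker:
    """A differential marker with its provenance and direction of change."""

    id: str
    source: str  # clinical | transcriptome | metabolome
    direction: str  # up | down
    tier: str = "significant"  # discriminant | significant


@dataclass
class MarkerSet:
    """Collection of differential markers feeding the network stage."""

    markers: list[Marker] = field(default_factory=list)

    def ids(self, tier: str | None = None) -> set[str]:
        return {m.id for m in self.markers if tier is None or m.tier == tier}

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def add(self, id: str, source: str, direction: str, tier: str = "significant") -> None:
        self.markers.append(Marker(id, source, direction, tier))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.id, m.source, m.direction, m.tier) for m in self.markers],
            columns=["id", "source", "direction", "tier"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerSet":
        ms = cls()
        for _, row in df.iterrows():
            ms.add(str(row["id"]), str(row["source"]), str(row["direction"]), str(row.get("tier", "significant")))
        return ms


@dataclass
class PathwayLibrary:
    """Pathway -> member set mapping with optional per-pathway graphs.

    ``graphs`` maps pathway name to an undirected networkx Graph over the
    pathway's members; used for the topological impact score.
    """

    members: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    graphs: dict[str, nx.Graph] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mem in self.members.items():
            if not mem:
                raise ValidationError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


class HeteroNetwork:
    """Typed directed network of compounds, proteins, metabolites, pathways, phenotypes.

    Thin wrapper over an nx.DiGraph; every node carries a ``kind`` attribute
    from the closed kind set and optionally an anatomical ``context`` label.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()
        self.validate()

    def validate(self) -> None:
        for n, d in self.graph.nodes(data=True):
            kind = d.get("kind")
            if kind not in NODE_KINDS:
                raise ValidationError(f"node {n!r} has unknown kind {kind!r}")
        for u, v in self.graph.edges():
            if u == v:
                raise ValidationError(f"self-loop on {u!r} not allowed")

    def add_node(self, node_id: str, kind: str, context: str | None = None) -> None:
        if kind not in NODE_KINDS:
            raise ValidationError(f"unknown kind {kind!r} for node {node_id!r}")
        attrs = {"kind": kind}
        if context is not None:
            attrs["context"] = context
        self.graph.add_node(node_id, **attrs)

    def add_edge(self, src: str, dst: str, relation: str = "association",
                 provenance: str = "database") -> None:
        if src == dst:
            raise ValidationError(f"self-loop on {src!r} not allowed")
        for n in (src, dst):
            if n not in self.graph:
                raise ValidationError(f"edge endpoint {n!r} not declared as a node")
        self.graph.add_edge(src, dst, relation=relation, provenance=provenance)

    def kind_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == kind}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeteroNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        for n in self.graph.nodes:
            if self.graph.nodes[n].get("kind") != other.graph.nodes[n].get("kind"):
                return False
        return True


@dataclass
class Subnetwork:
    """Shortest-path-retained slice of a parent network for one phenotype."""

    parent: HeteroNetwork
    graph: nx.DiGraph
    phenotype: str
    paths: list[list[str]] = field(default_factory=list)

    @property
    def compounds(self) -> set[str]:
        return {n for n in self.graph.nodes if self.parent.kind_of(n) == "compound"}

    @property
    def targets(self) -> set[str]:
        """Protein/metabolite nodes directly hit by a retained compound."""
        out: set[str] = set()
        for c in self.compounds:
            for t in self.graph.successors(c):
                if self.parent.kind_of(t) in ("protein", "metabolite"):
                    out.add(t)
        return out


@dataclass
class CTPNetwork:
    """Component-target-pathway network: compounds, targets, pathways, annotated edges."""

    graph: nx.DiGraph

    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == kind}

    @property
    def compounds(self) -> set[str]:
        return self.nodes_of_kind("compound")

    @property
    def pathways(self) -> set[str]:
        return self.nodes_of_kind("pathway")

    @property
    def targets(self) -> set[str]:
        return self.nodes_of_kind("protein") | self.nodes_of_kind("metabolite")
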