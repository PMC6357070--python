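"""File I/O: network edge-list TSV, Cytoscape SIF/GraphML, GMT pathway
libraries, and the tabular omics/clinical formats.

The network TSV dialect is five columns with a header:
``source  source_kind  relation  target  target_kind``. SIF and GraphML
exports preserve node ids, kinds (as attributes) and edge relations for
Cytoscape import; kind-specific shape hints follow the convention proteins
= round, metabolites = triangle.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    HeteroNetwork,
    MetaboliteTable,
    NODE_KINDS,
    PathwayLibrary,
    SHAPE_HINTS,
    ValidationError,
)

_HEADER = ["source", "source_kind", "relation", "target", "target_kind"]


def write_network(net: HeteroNetwork, path, fmt: str = "tsv") -> None:
    """Write a network as edge-list TSV, Cytoscape SIF, or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(_HEADER)
            for u, v, d in sorted(net.graph.edges(data=True)):
                w.writerow([u, net.kind_of(u), d.get("relation", "association"),
                            v, net.kind_of(v)])
            # isolated nodes kept on loopback lines so the round trip is lossless
            isolated = [n for n in sorted(net.graph.nodes) if net.graph.degree(n) == 0]
            for n in isolated:
                w.writerow([n, net.kind_of(n), "_node_", "", ""])
    elif fmt == "sif":
        with path.open("w") as fh:
            for u, v, d in sorted(net.graph.edges(data=True)):
                fh.write(f"{u}\t{d.get('relation', 'association')}\t{v}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, kind=d["kind"], shape=SHAPE_HINTS[d["kind"]])
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, relation=d.get("relation", "association"))
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")


def read_network(path) -> HeteroNetwork:
    """Read the five-column edge-list TSV back into a HeteroNetwork."""
    net = HeteroNetwork()
    pending: list[tuple[int, str, str, str]] = []
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _HEADER:
            raise ValidationError(f"unexpected network TSV header: {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0]:
                continue
            src, src_kind, relation, dst, dst_kind = row[:5]
            if src_kind not in NODE_KINDS:
                raise ValidationError(f"line {lineno}: unknown kind {src_kind!r}")
            net.add_node(src, src_kind)
            if relation == "_node_" and not dst:
                continue
            if dst_kind not in NODE_KINDS:
                raise ValidationError(f"line {lineno}: unknown kind {dst_kind!r}")
            net.add_node(dst, dst_kind)
            pending.append((lineno, src, relation, dst))
    for lineno, src, relation, dst in pending:
        net.add_edge(src, dst, relation=relation)
    return net


def write_node_attributes(net: HeteroNetwork, path) -> None:
    """Node-attribute CSV for Cytoscape: id, kind, shape hint."""
    rows = [
        (n, net.kind_of(n), SHAPE_HINTS[net.kind_of(n)])
        for n in sorted(net.graph.nodes)
    ]
    pd.DataFrame(rows, columns=["id", "kind", "shape"]).to_csv(path, index=False)


def write_gmt(members: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    """GMT dialect: pathway <tab> description <tab> member1 <tab> member2 ..."""
    descriptions = descriptions or {}
    with Path(path).open("w") as fh:
        for name in sorted(members):
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + sorted(members[name])) + "\n")


def read_gmt(path) -> PathwayLibrary:
    members: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line needs >= 3 fields: {line!r}")
            members[parts[0]] = set(parts[2:])
            descriptions[parts[0]] = parts[1]
    return PathwayLibrary(members, descriptions)


def read_pathway_graphs(path) -> dict[str, nx.Graph]:
    """Pathway-graph edge list TSV: pathway <tab> node_a <tab> node_b."""
    graphs: dict[str, nx.Graph] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValidationError(f"pathway graph line needs 3 fields: {line!r}")
            name, a, b = parts
            graphs.setdefault(name, nx.Graph()).add_edge(a, b)
    return graphs


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Expression CSV: first data row is the group label per sample."""
    _write_grouped(matrix.values, matrix.groups, path, index_name="gene")


def read_expression(path) -> ExpressionMatrix:
    values, groups = _read_grouped(path)
    return ExpressionMatrix(values, groups)


def write_metabolites(table: MetaboliteTable, path) -> None:
    _write_grouped(table.values, table.groups, path, index_name="metabolite")


def read_metabolites(path) -> MetaboliteTable:
    values, groups = _read_grouped(path)
    return MetaboliteTable(values, groups)


def _write_grouped(values: pd.DataFrame, groups: pd.Series, path, index_name: str) -> None:
    out = values.copy()
    out.index.name = index_name
    header = pd.DataFrame([groups.to_numpy()], index=pd.Index(["__group__"], name=index_name),
                          columns=values.columns)
    pd.concat([header, out]).to_csv(path)


def _read_grouped(path) -> tuple[pd.DataFrame, pd.Series]:
    raw = pd.read_csv(path, index_col=0)
    if "__group__" not in raw.index:
        raise ValidationError("grouped CSV is missing the __group__ row")
    groups = raw.loc["__group__"].astype(str)
    values = raw.drop(index="__group__").astype(float)
    return values, pd.Series(groups, index=raw.columns)
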