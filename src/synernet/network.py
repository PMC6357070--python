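"""Heterogeneous-network integration stage.

Given the typed directed network, a set of bioactive compounds and a set of
differential markers curated to a phenotype, the stage retains the union of
all directed shortest paths (bounded length) from compounds to marker
nodes, summarizes per-compound target sets and per-target compound
connectivity, enriches the retained genes/metabolites against a pathway
library (one-sided Fisher exact, BH-FDR), and assembles the tripartite
component-target-pathway network for Cytoscape export.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .datatypes import (
    CTPNetwork,
    HeteroNetwork,
    MarkerSet,
    PathwayLibrary,
    Subnetwork,
    ValidationError,
)
from .enrich import overrepresentation


def shortest_paths(
    network: HeteroNetwork,
    sources: set[str],
    sinks: set[str],
    max_len: int = 3,
    directed: bool = True,
) -> list[list[str]]:
    """All directed shortest paths source -> sink with length <= max_len.

    For each (source, sink) pair every shortest path is kept if its length
    (edge count) is within ``max_len``; unreachable pairs and pairs whose
    shortest path exceeds the bound are silently omitted. With
    ``directed=False`` edge direction is ignored.
    """
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    missing = (sources | sinks) - set(network.graph.nodes)
    if missing:
        raise ValidationError(f"nodes absent from network: {sorted(missing)[:5]}")
    g = network.graph if directed else network.graph.to_undirected(as_view=True)
    paths: list[list[str]] = []
    for s in sorted(sources):
        # single-source BFS gives all shortest distances at once
        lengths = nx.single_source_shortest_path_length(g, s, cutoff=max_len)
        for t in sorted(sinks):
            if t == s or t not in lengths:
                continue
            paths.extend(nx.all_shortest_paths(g, s, t))
    return paths


def extract_subnetwork(
    network: HeteroNetwork,
    compounds: set[str],
    markers: MarkerSet | set[str],
    phenotype: str,
    max_len: int = 3,
    directed: bool = True,
) -> Subnetwork:
    """Union of bounded shortest paths from compounds to phenotype markers.

    ``markers`` may be a MarkerSet or a plain id set; only marker ids
    present in the network and linked (directly) to the phenotype node are
    used as sinks. Compounds without any admissible path are dropped.
    """
    if phenotype not in network.graph:
        raise ValidationError(f"phenotype {phenotype!r} absent from network")
    for c in compounds:
        if c in network.graph and network.kind_of(c) != "compound":
            raise ValidationError(f"{c!r} is not a compound node")
    marker_ids = markers.ids() if isinstance(markers, MarkerSet) else set(markers)
    sinks = {
        m
        for m in marker_ids
        if m in network.graph and network.graph.has_edge(m, phenotype)
    }
    sources = {c for c in compounds if c in network.graph}
    paths = shortest_paths(network, sources, sinks, max_len=max_len, directed=directed)
    sub = nx.DiGraph()
    for path in paths:
        for n in path:
            sub.add_node(n, **network.graph.nodes[n])
        for u, v in zip(path, path[1:]):
            if network.graph.has_edge(u, v):
                sub.add_edge(u, v, **network.graph.edges[u, v])
            else:  # undirected fallback traversed the edge backwards
                sub.add_edge(v, u, **network.graph.edges[v, u])
    return Subnetwork(parent=network, graph=sub, phenotype=phenotype, paths=paths)


def compound_target_map(sub: Subnetwork) -> dict[str, set[str]]:
    """Per-compound direct protein/metabolite targets in the retained subgraph."""
    if sub.graph.number_of_nodes() == 0:
        return {}
    out: dict[str, set[str]] = {}
    for c in sorted(sub.compounds):
        targets = {
            t
            for t in sub.graph.successors(c)
            if sub.parent.kind_of(t) in ("protein", "metabolite")
        }
        if targets:
            out[c] = targets
    return out


def target_connectivity(sub: Subnetwork) -> dict[str, set[str]]:
    """Inverse map: target -> set of compounds that hit it directly."""
    inv: dict[str, set[str]] = {}
    for c, targets in compound_target_map(sub).items():
        for t in sorted(targets):
            inv.setdefault(t, set()).add(c)
    return inv


def enrich_pathways(
    hit_set: set[str],
    library: PathwayLibrary,
    universe: set[str],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """One-sided Fisher exact pathway enrichment with BH-FDR flagging.

    Returns ``pathway, hits, size, p, q, enriched`` sorted by p; rows with
    q < fdr are flagged enriched.
    """
    if not (0 < fdr <= 1):
        raise ValidationError("fdr must be in (0, 1]")
    df = overrepresentation(hit_set, library, universe)
    df["enriched"] = df["q"] < fdr if len(df) else []
    return df


def assemble_ctp(
    sub: Subnetwork,
    enrichment: pd.DataFrame | None = None,
    curated_links: list[tuple[str, str]] | None = None,
    library: PathwayLibrary | None = None,
) -> CTPNetwork:
    """Assemble the component-target-pathway network.

    Compound-target edges come from the subnetwork. Target-pathway edges
    come from curated (target, pathway) links, and/or — when an enrichment
    table plus the pathway library are supplied — from membership of a
    retained target in a pathway flagged enriched. Pathway nodes that end
    up isolated are dropped; every retained target connects to at least one
    compound by construction.
    """
    ct = compound_target_map(sub)
    g = nx.DiGraph()
    for c, targets in ct.items():
        g.add_node(c, kind="compound")
        for t in targets:
            g.add_node(t, kind=sub.parent.kind_of(t))
            g.add_edge(c, t, relation="targets")
    targets_present = {n for n, d in g.nodes(data=True) if d["kind"] != "compound"}
    links: list[tuple[str, str, str]] = []
    if curated_links:
        links.extend((t, p, "curated") for t, p in curated_links)
    if enrichment is not None and len(enrichment) and library is not None:
        for _, row in enrichment[enrichment["enriched"]].iterrows():
            name = str(row["pathway"])
            for t in sorted(targets_present & library.members.get(name, set())):
                links.append((t, name, "enriched"))
    for t, p, prov in links:
        if t not in targets_present:
            continue
        g.add_node(p, kind="pathway", provenance=prov)
        g.add_edge(t, p, relation="member_of")
    isolated = [
        n for n, d in g.nodes(data=True) if d["kind"] == "pathway" and g.degree(n) == 0
    ]
    g.remove_nodes_from(isolated)
    return CTPNetwork(g)
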