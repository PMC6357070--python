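"""Network I/O round trips, shortest-path search against a brute-force
oracle, subnetwork extraction, connectivity summaries and CTP assembly."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import all_shortest_paths_bruteforce
from synernet import netio
from synernet.datatypes import HeteroNetwork, MarkerSet, PathwayLibrary, ValidationError
from synernet.fixtures import vascular_fixture
from synernet.network import (
    assemble_ctp,
    compound_target_map,
    enrich_pathways,
    extract_subnetwork,
    shortest_paths,
    target_connectivity,
)
from synernet.synthetic import NetworkGenConfig, gen_hetero_network


class TestNetworkIO:
    def test_tsv_round_trip(self, fixture_network, tmp_path):
        p = tmp_path / "net.tsv"
        netio.write_network(fixture_network, p, fmt="tsv")
        assert netio.read_network(p) == fixture_network

    def test_sif_dialect(self, tmp_path):
        net = HeteroNetwork()
        net.add_node("EA", "compound")
        net.add_node("NOS3", "protein")
        net.add_edge("EA", "NOS3", relation="targets")
        p = tmp_path / "net.sif"
        netio.write_network(net, p, fmt="sif")
        assert p.read_text().strip() == "EA\ttargets\tNOS3"

    def test_graphml_preserves_kinds_and_relations(self, fixture_network, tmp_path):
        p = tmp_path / "net.graphml"
        netio.write_network(fixture_network, p, fmt="graphml")
        g = nx.read_graphml(p)
        assert set(g.nodes) == set(fixture_network.graph.nodes)
        assert g.nodes["succinate"]["kind"] == "metabolite"
        assert g.nodes["succinate"]["shape"] == "triangle"
        assert g.edges["ellagic acid", "NOS3"]["relation"] == "targets"

    def test_empty_network_round_trip(self, tmp_path):
        p = tmp_path / "empty.tsv"
        netio.write_network(HeteroNetwork(), p, fmt="tsv")
        assert netio.read_network(p).n_nodes == 0

    def test_unknown_kind_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("source\tsource_kind\trelation\ttarget\ttarget_kind\n"
                     "A\tgene\ttargets\tB\tprotein\n")
        with pytest.raises(ValidationError, match="line 2"):
            netio.read_network(p)

    def test_gmt_round_trip(self, tmp_path):
        members = {"pw a": {"x", "y"}, "pw b": {"z"}}
        p = tmp_path / "lib.gmt"
        netio.write_gmt(members, p)
        lib = netio.read_gmt(p)
        assert lib.members == members


class TestShortestPaths:
    def test_chain(self):
        net = HeteroNetwork()
        for n, k in [("A", "compound"), ("B", "protein"), ("C", "phenotype")]:
            net.add_node(n, k)
        net.add_edge("A", "B")
        net.add_edge("B", "C")
        assert shortest_paths(net, {"A"}, {"C"}) == [["A", "B", "C"]]

    def test_disconnected_pair_empty(self):
        net = HeteroNetwork()
        net.add_node("A", "compound")
        net.add_node("C", "phenotype")
        assert shortest_paths(net, {"A"}, {"C"}) == []

    def test_max_len_bound(self):
        net = HeteroNetwork()
        chain = ["A", "B", "C", "D", "E"]
        for i, n in enumerate(chain):
            net.add_node(n, "protein" if 0 < i < 4 else ("compound" if i == 0 else "phenotype"))
        for u, v in zip(chain, chain[1:]):
            net.add_edge(u, v)
        assert shortest_paths(net, {"A"}, {"E"}, max_len=3) == []
        assert shortest_paths(net, {"A"}, {"E"}, max_len=4) == [chain]

    def test_invalid_max_len(self, fixture_network):
        with pytest.raises(ValidationError):
            shortest_paths(fixture_network, set(), set(), max_len=0)

    @pytest.mark.parametrize("seed", [9, 10, 11])
    def test_matches_bruteforce_on_random_graph(self, seed):
        cfg = NetworkGenConfig(n_compounds=5, n_proteins=15, n_metabolites=5,
                               n_pathways=2, n_phenotypes=3, edge_density=0.12, seed=seed)
        net = gen_hetero_network(cfg)
        sources = net.nodes_of_kind("compound")
        sinks = net.nodes_of_kind("phenotype")
        got = shortest_paths(net, sources, sinks, max_len=4)
        expected = all_shortest_paths_bruteforce(net.graph, sources, sinks, 4)
        assert sorted(map(tuple, got)) == sorted(map(tuple, expected))


class TestExtractSubnetwork:
    def test_fixture_reproduces_published_counts(self, fixture_network, phenotype):
        fx = vascular_fixture()
        sub = extract_subnetwork(
            fixture_network, fixture_network.nodes_of_kind("compound"),
            set(fx.targets), phenotype)
        ct = compound_target_map(sub)
        assert len(ct) == 6
        assert len(set().union(*ct.values())) == 15
        assert sum(len(v) for v in ct.values()) == 39

    def test_compound_without_path_dropped(self, fixture_network, phenotype):
        fx = vascular_fixture()
        sub = extract_subnetwork(
            fixture_network, fixture_network.nodes_of_kind("compound"),
            set(fx.targets), phenotype)
        assert "danshensu" not in sub.graph.nodes

    def test_planted_toy_equals_construction(self):
        net = HeteroNetwork()
        net.add_node("c1", "compound")
        net.add_node("c2", "compound")
        net.add_node("t", "protein")
        net.add_node("ph", "phenotype")
        net.add_edge("c1", "t")
        net.add_edge("c2", "t")
        net.add_edge("t", "ph")
        sub = extract_subnetwork(net, {"c1", "c2"}, {"t"}, "ph")
        assert set(sub.graph.edges) == {("c1", "t"), ("c2", "t")}

    def test_missing_phenotype_rejected(self, fixture_network):
        with pytest.raises(ValidationError):
            extract_subnetwork(fixture_network, set(), set(), "no-such-phenotype")

    def test_max_len_monotonicity(self, fixture_network, phenotype):
        fx = vascular_fixture()
        compounds = fixture_network.nodes_of_kind("compound")
        nodes = [
            set(extract_subnetwork(fixture_network, compounds, set(fx.targets),
                                   phenotype, max_len=k).graph.nodes)
            for k in (1, 2, 3)
        ]
        assert nodes[0] <= nodes[1] <= nodes[2]

    def test_every_edge_on_a_shortest_path(self, fixture_network, phenotype):
        fx = vascular_fixture()
        sub = extract_subnetwork(fixture_network, fixture_network.nodes_of_kind("compound"),
                                 set(fx.targets), phenotype)
        on_path = set()
        for path in sub.paths:
            on_path.update(zip(path, path[1:]))
        assert set(sub.graph.edges) <= on_path


class TestConnectivity:
    def test_fixture_target_degrees(self, fixture_network, phenotype):
        fx = vascular_fixture()
        sub = extract_subnetwork(fixture_network, fixture_network.nodes_of_kind("compound"),
                                 set(fx.targets), phenotype)
        tc = target_connectivity(sub)
        for t in ("NOS3", "SUCLG1", "succinate"):
            assert len(tc[t]) == 6
        assert len(tc["CYP1A1"]) == 4  # EA, PCA, CT, TI

    def test_inverse_consistency(self, fixture_network, phenotype):
        fx = vascular_fixture()
        sub = extract_subnetwork(fixture_network, fixture_network.nodes_of_kind("compound"),
                                 set(fx.targets), phenotype)
        ct, tc = compound_target_map(sub), target_connectivity(sub)
        assert sum(len(v) for v in ct.values()) == sum(len(v) for v in tc.values())

    def test_empty_subnetwork_empty_maps(self, fixture_network):
        sub = extract_subnetwork(fixture_network, set(), set(),
                                 "vascular endothelial dilation")
        assert compound_target_map(sub) == {}
        assert target_connectivity(sub) == {}


class TestAssembleCtp:
    def _sub(self, fixture_network, phenotype):
        fx = vascular_fixture()
        return fx, extract_subnetwork(
            fixture_network, fixture_network.nodes_of_kind("compound"),
            set(fx.targets), phenotype)

    def test_fixture_curated_links_six_pathways(self, fixture_network, phenotype):
        fx, sub = self._sub(fixture_network, phenotype)
        ctp = assemble_ctp(sub, curated_links=fx.target_pathway_edges)
        assert len(ctp.pathways) == 6
        assert len(ctp.compounds) == 6
        assert len(ctp.targets) == 15

    def test_nos3_single_pathway_edge(self, fixture_network, phenotype):
        fx, sub = self._sub(fixture_network, phenotype)
        ctp = assemble_ctp(sub, curated_links=fx.target_pathway_edges)
        succ = [p for p in ctp.graph.successors("NOS3")
                if ctp.graph.nodes[p]["kind"] == "pathway"]
        assert succ == ["arginine and proline metabolism"]

    def test_no_links_gives_bipartite_network(self, fixture_network, phenotype):
        _, sub = self._sub(fixture_network, phenotype)
        ctp = assemble_ctp(sub)
        assert len(ctp.pathways) == 0
        assert len(ctp.graph.edges) == 39

    def test_every_target_reaches_a_compound(self, fixture_network, phenotype):
        fx, sub = self._sub(fixture_network, phenotype)
        ctp = assemble_ctp(sub, curated_links=fx.target_pathway_edges)
        for t in ctp.targets:
            assert any(ctp.graph.has_edge(c, t) for c in ctp.compounds)

    def test_enrichment_membership_links(self, fixture_network, phenotype):
        _, sub = self._sub(fixture_network, phenotype)
        universe = (fixture_network.nodes_of_kind("protein")
                    | fixture_network.nodes_of_kind("metabolite"))
        lib = PathwayLibrary({"hit pw": {"NOS3", "SUCLG1", "succinate", "EDN1", "ARG2"},
                              "cold pw": {"TP53", "EGFR"}})
        enr = enrich_pathways({"NOS3", "SUCLG1", "succinate", "EDN1", "ARG2"},
                              lib, universe, fdr=0.05)
        ctp = assemble_ctp(sub, enrichment=enr, library=lib)
        assert ctp.pathways == {"hit pw"}
        assert ctp.graph.has_edge("NOS3", "hit pw")
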