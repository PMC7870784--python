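"""PMSN assembly (annotation rules, bipartiteness) and topology analysis."""

import networkx as nx
import numpy as np
import pytest

from oracles import betweenness_by_path_enumeration
from pmsnet import build_pmsn, fit_power_law, hub_report, topology
from pmsnet.io import MIRNA_GENE, TARGET_SITE, collection_from_sets
from pmsnet.mirna import MirnaPathwayPair
from pmsnet.mirsnp import MiRSNPRecord
from pmsnet.pmsn import PMSNGraph


def _pair(mirna, pathway, p_adj=1e-5):
    return MirnaPathwayPair(mirna=mirna, pathway=pathway, x=5, n=20, j=30, m=1000,
                            p=p_adj / 10, p_adj=p_adj)


def _snp(rsid, mirna, gene=None, cls=TARGET_SITE):
    return MiRSNPRecord(rsid=rsid, snp_class=cls, mirna=mirna,
                        gene=gene if cls == TARGET_SITE else None,
                        databases=frozenset({"db1", "db2"}), validated=False)


COLL = collection_from_sets({"pw1": ["GA", "GB"], "pw2": ["GC", "GD"]})


class TestBuildPMSN:
    def test_empty_snp_sets_give_plain_bipartite_graph(self):
        pmsn = build_pmsn([_pair("hsa-mir-1", "pw1")], [], [], COLL)
        assert pmsn.graph.number_of_edges() == 1
        assert pmsn.graph.edges["hsa-mir-1", "pw1"]["snps"] == ()
        assert pmsn.graph.nodes["hsa-mir-1"]["snps"] == ()
        assert pmsn.unattached == ()

    def test_target_site_snp_annotates_matching_edge(self):
        pairs = [_pair("hsa-mir-1", "pw1"), _pair("hsa-mir-1", "pw2")]
        snp = _snp("rs10", "hsa-mir-1", gene="GA")
        pmsn = build_pmsn(pairs, [snp], [], COLL)
        assert pmsn.graph.edges["hsa-mir-1", "pw1"]["snps"] == (("rs10", "GA"),)
        assert pmsn.graph.edges["hsa-mir-1", "pw2"]["snps"] == ()

    def test_mirna_gene_snp_annotates_node(self):
        snp = _snp("rs11", "hsa-mir-1", cls=MIRNA_GENE)
        pmsn = build_pmsn([_pair("hsa-mir-1", "pw1")], [], [snp], COLL)
        assert pmsn.graph.nodes["hsa-mir-1"]["snps"] == ("rs11",)

    def test_unplaceable_snps_are_reported(self):
        pairs = [_pair("hsa-mir-1", "pw2")]
        stray_gene = _snp("rs12", "hsa-mir-1", gene="GA")  # GA not in pw2
        stray_mirna = _snp("rs13", "hsa-mir-9", cls=MIRNA_GENE)
        pmsn = build_pmsn(pairs, [stray_gene], [stray_mirna], COLL)
        assert {s.rsid for s in pmsn.unattached} == {"rs12", "rs13"}

    def test_unknown_pathway_id_is_error(self):
        with pytest.raises(KeyError, match="unknown pathway"):
            build_pmsn([_pair("hsa-mir-1", "nope")], [], [], COLL)

    def test_annotation_rule_matches_exhaustive_scan(self, default_bundle, default_result):
        pmsn = default_result.pmsn
        coll = default_bundle.pathways
        edge_snps = {
            (u, v) if pmsn.graph.nodes[u]["kind"] == "mirna" else (v, u): set(d["snps"])
            for u, v, d in pmsn.graph.edges(data=True)
        }
        # independent re-derivation of every edge annotation
        expected = {key: set() for key in edge_snps}
        for snp in default_result.target_site_snps:
            for (mirna, pathway) in expected:
                if snp.mirna == mirna and snp.gene in coll.genes(pathway):
                    expected[(mirna, pathway)].add((snp.rsid, snp.gene))
        assert edge_snps == expected

    def test_bipartiteness_and_degree_identity(self, default_result):
        pmsn = default_result.pmsn
        pmsn.assert_bipartite()
        degs = dict(pmsn.graph.degree())
        mirna_deg = sum(degs[n] for n in pmsn.mirna_nodes)
        pathway_deg = sum(degs[n] for n in pmsn.pathway_nodes)
        assert mirna_deg == pathway_deg == pmsn.graph.number_of_edges()


def _graph_from_edges(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_node(u, kind="mirna", snps=())
        g.add_node(v, kind="pathway")
        g.add_edge(u, v, snps=())
    return PMSNGraph(graph=g)


class TestTopology:
    def test_star_hub_betweenness(self):
        pmsn = _graph_from_edges([("hub", f"leaf{i}") for i in range(4)])
        topo = topology(pmsn)
        assert topo.degrees["hub"] == 4
        assert topo.betweenness["hub"] == pytest.approx(1.0)
        assert all(topo.betweenness[f"leaf{i}"] == 0.0 for i in range(4))

    def test_path_midpoint_betweenness(self):
        pmsn = _graph_from_edges([("a", "mid"), ("c", "mid")])
        # undirected 3-node path: the middle carries the single shortest path
        topo = topology(pmsn)
        assert topo.betweenness["mid"] == pytest.approx(1.0)

    def test_single_node_graph_has_zero_betweenness(self):
        g = nx.Graph()
        g.add_node("only", kind="mirna", snps=())
        topo = topology(PMSNGraph(graph=g))
        assert topo.betweenness == {"only": 0.0}

    def test_betweenness_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            n_mirna = int(rng.integers(4, 16))
            n_path = int(rng.integers(3, 15))
            edges = [
                (f"m{i}", f"p{j}")
                for i in range(n_mirna)
                for j in range(n_path)
                if rng.random() < 0.25
            ]
            if not edges:
                continue
            pmsn = _graph_from_edges(edges)
            topo = topology(pmsn)
            oracle = betweenness_by_path_enumeration(pmsn.graph)
            for node, expected in oracle.items():
                assert topo.betweenness[node] == pytest.approx(expected, abs=1e-9), node


class TestPowerLawFit:
    def test_exact_power_law_histogram_recovered(self):
        # frequencies 36/d^2 at degrees 1, 2, 3, 6: an exact exponent-2 law
        hist = {1: 36, 2: 9, 3: 4, 6: 1}
        exponent, r2 = fit_power_law(hist)
        assert exponent == pytest.approx(2.0, abs=0.05)
        assert r2 >= 0.99

    def test_degenerate_histogram_returns_nan(self):
        exponent, r2 = fit_power_law({3: 10})
        assert np.isnan(exponent) and np.isnan(r2)


class TestHubReport:
    def test_no_mirna_above_threshold_gives_empty_section(self):
        pmsn = _graph_from_edges([("m1", "p1"), ("m1", "p2"), ("m2", "p1")])
        report = hub_report(topology(pmsn), mirna_degree_gt=3)
        assert report["mirnas"].empty
        assert not report["pathways"].empty

    def test_highest_degree_mirna_heads_ranking(self):
        edges = [("big", f"p{i}") for i in range(10)] + [("small", "p0"), ("mid", "p1"),
                                                         ("mid", "p2"), ("mid", "p3"),
                                                         ("mid", "p4")]
        report = hub_report(topology(_graph_from_edges(edges)), mirna_degree_gt=3)
        assert report["mirnas"]["node"].tolist() == ["big", "mid"]

    def test_planted_hubs_recovered(self, default_bundle, default_result):
        got = default_result.hubs["mirnas"]["node"].tolist()
        assert got == list(default_bundle.truth.hub_mirnas)
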