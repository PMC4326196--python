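import itertools

import networkx as nx
import numpy as np
import pytest

from repliconpan.cluster import (
    SimilarityGraph,
    build_graph_from_hits,
    cluster_pipeline,
    filter_proteins,
    mcl_cluster,
)
from repliconpan.records import Gene, HitRecord


def _gene(gid, aa_len):
    prot = "M" + "K" * (aa_len - 1)
    cds = "ATG" + "AAA" * (aa_len - 1) + "TAA"
    return Gene(gid, "R1", 1, len(cds), "+", cds, prot)


class TestFilterProteins:
    def test_strictly_longer_than_threshold_kept(self):
        kept = filter_proteins([_gene("a", 51), _gene("b", 50), _gene("c", 120)])
        assert [g.gene_id for g in kept] == ["a", "c"]

    def test_empty_input(self):
        assert filter_proteins([]) == []


def _hit(q, s, pident, length, bits=100.0):
    return HitRecord(q, s, pident, length, 0, 0, 1, length, 1, length, 1e-20, bits)


class TestEdgeGating:
    LEN = {"a": 100, "b": 100}

    def test_identity_exactly_at_threshold_excluded(self):
        sg = build_graph_from_hits([_hit("a", "b", 70.0, 100)], self.LEN)
        assert sg.n_edges == 0

    def test_both_coverages_must_pass(self):
        # alignment covers 90% of a (len 100) but only 60% of b (len 150)
        lengths = {"a": 100, "b": 150}
        sg = build_graph_from_hits([_hit("a", "b", 85.0, 90)], lengths)
        assert sg.n_edges == 0

    def test_passing_pair_kept_and_symmetric(self):
        sg = build_graph_from_hits([_hit("a", "b", 85.0, 90)], self.LEN)
        assert sg.graph.has_edge("a", "b") and sg.graph.has_edge("b", "a")

    def test_reciprocal_hits_merged_by_better_score(self):
        hits = [_hit("a", "b", 85.0, 90, bits=100), _hit("b", "a", 85.0, 90, bits=150)]
        sg = build_graph_from_hits(hits, self.LEN)
        assert sg.graph["a"]["b"]["weight"] == 150


def _clique_graph(sizes):
    g = nx.Graph()
    node = 0
    for s in sizes:
        members = [f"n{node + i:03d}" for i in range(s)]
        node += s
        g.add_nodes_from(members)
        for u, v in itertools.combinations(members, 2):
            g.add_edge(u, v, weight=1.0)
    return SimilarityGraph(g, 70, 70)


class TestMCL:
    def test_two_disjoint_triangles_give_two_families(self):
        fams = mcl_cluster(_clique_graph([3, 3]))
        assert len(fams) == 2
        comps = {frozenset(c) for c in nx.connected_components(_clique_graph([3, 3]).graph)}
        assert {f.members for f in fams} == comps

    def test_single_isolated_node_is_singleton_family(self):
        fams = mcl_cluster(_clique_graph([1]))
        assert len(fams) == 1 and fams[0].size == 1

    @pytest.mark.parametrize("sizes", [(2, 4), (1, 5, 3), (6,), (2, 2, 2)])
    def test_clique_components_recovered(self, sizes):
        sg = _clique_graph(sizes)
        fams = mcl_cluster(sg)
        comps = {frozenset(c) for c in nx.connected_components(sg.graph)}
        assert {f.members for f in fams} == comps

    def test_invariant_to_uniform_weight_scaling(self):
        g1 = _clique_graph([3, 4, 2])
        g2 = _clique_graph([3, 4, 2])
        for u, v in g2.graph.edges:
            g2.graph[u][v]["weight"] *= 137.0
        assert {f.members for f in mcl_cluster(g1)} == {f.members for f in mcl_cluster(g2)}

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(30, 0.15, seed=9)
        sg = nx.Graph()
        sg.add_nodes_from(f"n{i:02d}" for i in range(30))
        for u, v in g.edges:
            sg.add_edge(f"n{u:02d}", f"n{v:02d}", weight=float(rng.uniform(0.5, 2)))
        fams = mcl_cluster(SimilarityGraph(sg, 70, 70))
        seen = set()
        for f in fams:
            assert not (f.members & seen)
            seen |= f.members
        assert seen == set(sg.nodes)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(_clique_graph([2]), inflation=1.0)


class TestClusterPipeline:
    def test_recovers_planted_families_exactly(self, small_sim, small_cluster):
        truth = small_sim.truth.genes.groupby("family_id")["gene_id"].apply(frozenset)
        planted = set(truth)
        recovered = {f.members for f in small_cluster.families}
        assert recovered == planted

    def test_order_invariance_up_to_relabeling(self, small_sim):
        genes = list(small_sim.genes)
        rng = np.random.default_rng(3)
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        a = cluster_pipeline(genes[:60])
        b = cluster_pipeline([g for g in shuffled if g in genes[:60]])
        assert {f.members for f in a.families} == {f.members for f in b.families}

    def test_removing_one_member_keeps_remaining_pair_clustered(self, small_sim):
        truth = small_sim.truth.genes
        fam3 = truth.groupby("family_id").filter(lambda d: len(d) == 3)["family_id"].iloc[0]
        members = set(truth.loc[truth["family_id"] == fam3, "gene_id"])
        drop = sorted(members)[0]
        keep = {g.gene_id for g in small_sim.genes} - {drop}
        res = cluster_pipeline([g for g in small_sim.genes if g.gene_id in keep])
        remaining = members - {drop}
        assert any(remaining <= f.members and f.members <= remaining for f in res.families)
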