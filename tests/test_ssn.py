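import math
import random

import pytest
from hypothesis import given, strategies as st

from gmcnet.seqio import AnnotationRow, SequenceRecord
from gmcnet.ssn import (
    ClusterAssignment,
    NetworkEdge,
    ScoringParams,
    SimilarityNetwork,
    all_pairs_edges,
    annotate_clusters,
    build_network,
    connected_components,
    edge_from_raw_score,
    pairwise_score,
    read_graphml,
    sweep_cutoffs,
    threshold_edges,
    write_graphml,
)
from conftest import AA, random_protein


def rec(sid, residues):
    return SequenceRecord(id=sid, residues=residues)


class TestPairwiseScore:
    def test_identical_sequences_full_identity(self):
        a, b = rec("a", "MKVLI" * 20), rec("b", "MKVLI" * 20)
        edge = pairwise_score(a, b)
        assert edge.percent_identity == pytest.approx(100.0)

    def test_karlin_altschul_closed_form(self):
        """A raw score giving S' = 50 bits with m = N = 100 yields
        E = 100 * 100 * 2^-50 ~= 8.88e-12."""
        scoring = ScoringParams()
        raw = (50.0 * math.log(2) + math.log(scoring.karlin_k)) / scoring.karlin_lambda
        edge = edge_from_raw_score("a", "b", raw, query_length=100,
                                   search_space=100, percent_identity=50.0)
        assert edge.bit_score == pytest.approx(50.0, abs=1e-9)
        assert edge.evalue == pytest.approx(8.881784e-12, rel=1e-5)
        assert edge.alignment_score == pytest.approx(-math.log10(edge.evalue))

    def test_endpoints_sorted_regardless_of_argument_order(self):
        a, b = rec("zeta", "MKVLITTA" * 15), rec("alpha", "MKVLITTG" * 15)
        edge = pairwise_score(a, b)
        assert (edge.a, edge.b) == ("alpha", "zeta")

    @given(st.integers(0, 10_000))
    def test_symmetric_under_argument_swap(self, seed):
        rng = random.Random(seed)
        a = rec("a", random_protein(rng, rng.randint(30, 80)))
        b = rec("b", random_protein(rng, rng.randint(30, 80)))
        forward, backward = pairwise_score(a, b), pairwise_score(b, a)
        assert forward == backward

    def test_zero_length_rejected(self):
        with pytest.raises(Exception):
            pairwise_score(rec("a", ""), rec("b", "MK"))

    def test_evalue_floor_keeps_log_finite(self):
        edge = edge_from_raw_score("a", "b", 1e5, 550, 1e5, 100.0)
        assert edge.evalue == 1e-180
        assert edge.alignment_score == pytest.approx(180.0)


class TestBuildNetwork:
    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            build_network([rec("a", "MKVLI" * 30)], 10)

    def test_cutoff_zero_admits_evalue_up_to_one(self):
        rng = random.Random(3)
        records = [rec(f"s{i}", random_protein(rng, 60)) for i in range(4)]
        edges = all_pairs_edges(records)
        net = build_network(records, 0, edges=edges)
        assert {(e.a, e.b) for e in net.edges} == \
            {(e.a, e.b) for e in edges if e.evalue <= 1.0}

    def test_duplicated_sequences_form_complete_graph(self):
        body = "MKVLITTAGDERW" * 30
        records = [rec(f"s{i}", body) for i in range(4)]
        net = build_network(records, 85)
        assert len(net.edges) == 6

    def test_isolated_nodes_kept(self, small_sim):
        records = [r for r in small_sim.records][:6]
        net = build_network(records, 500)  # unreachable stringency: no edges
        assert net.edges == [] and len(net.nodes) == 6


class TestComponents:
    def test_edgeless_network_all_singletons(self):
        net = SimilarityNetwork(nodes={"a", "b", "c", "d"}, edges=[], cutoff_exponent=85)
        clusters = connected_components(net)
        assert [len(c.members) for c in clusters] == [1, 1, 1, 1]

    def test_path_is_one_cluster(self):
        def e(a, b):
            return NetworkEdge(a=a, b=b, bit_score=1, evalue=1e-90,
                               percent_identity=50, alignment_score=90)
        net = SimilarityNetwork(nodes={"A", "B", "C"},
                                edges=[e("A", "B"), e("B", "C")],
                                cutoff_exponent=85)
        (cluster,) = connected_components(net)
        assert cluster.members == {"A", "B", "C"}

    def test_matches_union_find_oracle_on_random_graph(self):
        rng = random.Random(11)
        nodes = [f"n{i:02d}" for i in range(50)]
        pairs = {tuple(sorted(rng.sample(nodes, 2))) for _ in range(60)}
        edges = [NetworkEdge(a=a, b=b, bit_score=1, evalue=1e-90,
                             percent_identity=50, alignment_score=90)
                 for a, b in pairs]
        net = SimilarityNetwork(nodes=set(nodes), edges=edges, cutoff_exponent=85)

        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find(a)] = find(b)
        oracle = {}
        for n in nodes:
            oracle.setdefault(find(n), set()).add(n)
        got = {frozenset(c.members) for c in connected_components(net)}
        assert got == {frozenset(s) for s in oracle.values()}

    def test_cluster_ids_by_size_then_smallest_member(self):
        def e(a, b):
            return NetworkEdge(a=a, b=b, bit_score=1, evalue=1e-90,
                               percent_identity=50, alignment_score=90)
        net = SimilarityNetwork(nodes={"a", "b", "p", "q", "z"},
                                edges=[e("p", "q"), e("a", "b")],
                                cutoff_exponent=85)
        clusters = connected_components(net)
        assert [sorted(c.members) for c in clusters] == \
            [["a", "b"], ["p", "q"], ["z"]]


class TestSweep:
    def test_snapshot_count_85_to_140_step_5(self, small_sim):
        records = small_sim.records
        net = build_network(records, 85)
        snaps = sweep_cutoffs(net, 85, 140, 5)
        assert len(snaps) == 12
        assert [s[0] for s in snaps] == list(range(85, 145, 5))

    def test_single_snapshot_when_start_equals_end(self, small_sim):
        net = build_network(small_sim.records, 85)
        assert len(sweep_cutoffs(net, 85, 85, 5)) == 1

    def test_edges_shrink_and_components_grow(self, small_sim):
        net = build_network(small_sim.records, 60)
        snaps = sweep_cutoffs(net, 60, 160, 10)
        previous_edges, previous_count = None, 0
        for exponent, clusters in snaps:
            edges = {(e.a, e.b) for e in threshold_edges(net.edges, exponent)}
            if previous_edges is not None:
                assert edges <= previous_edges
            assert len(clusters) >= previous_count
            previous_edges, previous_count = edges, len(clusters)


class TestAnnotateClusters:
    def make(self, members):
        return ClusterAssignment(cluster_id=0, members=set(members))

    def test_single_function_label(self):
        ann = {"a": AnnotationRow(id="a", function_label="GOx"),
               "b": AnnotationRow(id="b", function_label="GOx")}
        (labelled,) = annotate_clusters([self.make({"a", "b", "c"})], ann)
        assert labelled.label == "GOx"

    def test_composite_label_first_appearance_order(self):
        ann = {"a": AnnotationRow(id="a", function_label="GOx"),
               "b": AnnotationRow(id="b", function_label="GDH")}
        (labelled,) = annotate_clusters([self.make({"a", "b"})], ann)
        assert labelled.label == "GOx–GDH"

    def test_unannotated(self):
        (labelled,) = annotate_clusters([self.make({"x", "y"})], {})
        assert labelled.label == "unannotated"


class TestExport:
    def test_graphml_round_trip(self, tmp_path, small_sim):
        records = small_sim.records[:8]
        net = build_network(records, 20)
        path = tmp_path / "net.graphml"
        write_graphml(net, path)
        back = read_graphml(path)
        assert back.nodes == net.nodes
        assert {(e.a, e.b) for e in back.edges} == {(e.a, e.b) for e in net.edges}
        by_pair = {(e.a, e.b): e for e in net.edges}
        for e in back.edges:
            orig = by_pair[(e.a, e.b)]
            assert e.evalue == pytest.approx(orig.evalue)
            assert e.bit_score == pytest.approx(orig.bit_score)
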