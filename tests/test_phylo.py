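import random
from itertools import combinations

import numpy as np
import pytest

from gmcnet.msa import Msa
from gmcnet.phylo import (
    CladeConflictError,
    CladeDefinition,
    assign_clades,
    clade_profile,
    mean_percent_identity,
    midpoint_root,
    nj_tree,
    pairwise_identity_gap_excluded,
    patristic_distances,
    read_newick,
    root_to_leaf_distances,
    write_newick,
)
from gmcnet.seqio import AnnotationRow


def matrix_from_tree(newick):
    tree = read_newick(newick)
    pd = patristic_distances(tree)
    labels = sorted({x for pair in pd for x in pair})
    n = len(labels)
    M = np.zeros((n, n))
    for (a, b), d in pd.items():
        i, j = labels.index(a), labels.index(b)
        M[i, j] = M[j, i] = d
    return M, labels, pd


class TestMidpointRoot:
    def test_two_leaf_tree_roots_at_distance_two(self):
        tree = midpoint_root(read_newick("(A:1,B:3);"))
        dists = root_to_leaf_distances(tree)
        assert dists["A"] == pytest.approx(2.0, abs=1e-9)
        assert dists["B"] == pytest.approx(2.0, abs=1e-9)

    def test_farthest_pair_equidistant(self):
        tree = midpoint_root(read_newick("((A:5,B:1):1,(C:2,D:7):1);"))
        dists = root_to_leaf_distances(tree)
        # longest path A..D of length 14 -> both ends at 7
        assert dists["A"] == pytest.approx(7.0, abs=1e-9)
        assert dists["D"] == pytest.approx(7.0, abs=1e-9)

    def test_idempotent(self):
        once = midpoint_root(read_newick("((A:5,B:1):1,(C:2,D:7):1);"))
        twice = midpoint_root(once)
        assert root_to_leaf_distances(twice) == \
            pytest.approx(root_to_leaf_distances(once))

    def test_missing_branch_length_raises(self):
        with pytest.raises(ValueError):
            midpoint_root(read_newick("((A:1,B),C:2);"))

    def test_preserves_leaf_distances(self):
        newick = "((A:3,(B:1,C:2):2):1,(D:4,E:1):2);"
        before = patristic_distances(read_newick(newick))
        after = patristic_distances(midpoint_root(read_newick(newick)))
        for pair, d in before.items():
            assert after[pair] == pytest.approx(d, abs=1e-9)

    def test_minimises_max_root_to_leaf_depth(self):
        """Among all rootings, midpoint minimises the tree height; its height
        is half the diameter."""
        newick = "((A:2,B:6):1,((C:1,D:3):2,E:9):1);"
        tree = midpoint_root(read_newick(newick))
        pd = patristic_distances(read_newick(newick))
        diameter = max(pd.values())
        assert max(root_to_leaf_distances(tree).values()) == \
            pytest.approx(diameter / 2, abs=1e-9)


class TestNeighborJoining:
    def test_additive_five_taxon_distances_recovered(self):
        M, labels, pd = matrix_from_tree("((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);")
        tree = nj_tree(M, labels)
        recovered = patristic_distances(tree)
        for pair, d in pd.items():
            assert recovered[pair] == pytest.approx(d, abs=1e-9)

    def test_three_taxa_unique_topology(self):
        M = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(M, ["A", "B", "C"])
        recovered = patristic_distances(tree)
        assert recovered[("A", "B")] == pytest.approx(2.0)
        assert recovered[("A", "C")] == pytest.approx(3.0)
        assert recovered[("B", "C")] == pytest.approx(4.0)

    def test_ultrametric_matrix_midpoint_matches_ultrametric_root(self):
        M, labels, _ = matrix_from_tree(
            "(((A:1,B:1):1,C:2):1,(D:2.5,E:2.5):0.5);")
        rooted = midpoint_root(nj_tree(M, labels))
        dists = root_to_leaf_distances(rooted)
        assert all(d == pytest.approx(3.0, abs=1e-9) for d in dists.values())

    def test_asymmetric_matrix_rejected(self):
        M = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(M, ["A", "B", "C"])

    def test_nonzero_diagonal_rejected(self):
        M = np.array([[0.1, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(M, ["A", "B", "C"])


class TestAssignClades:
    TREE = "(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);"

    def test_mrca_spans_intermediate_leaves(self):
        (clade,) = assign_clades(read_newick(self.TREE), {"left": ["A", "C"]})
        assert clade.assigned_members == {"A", "B", "C"}

    def test_single_reference_clade_is_the_leaf(self):
        (clade,) = assign_clades(read_newick(self.TREE), {"solo": ["F"]})
        assert clade.assigned_members == {"F"}

    def test_interleaved_references_conflict(self):
        with pytest.raises(CladeConflictError):
            assign_clades(read_newick(self.TREE),
                          {"x": ["A", "C"], "y": ["B", "C"]})

    def test_invariant_to_reference_order(self):
        t = read_newick(self.TREE)
        first = assign_clades(t, {"c": ["A", "C"]})
        second = assign_clades(t, {"c": ["C", "A"]})
        assert first[0].assigned_members == second[0].assigned_members

    def test_explicit_member_override(self):
        override = CladeDefinition(name="manual", reference_ids=("A",),
                                   assigned_members={"A", "F"})
        (clade,) = assign_clades(read_newick(self.TREE), [override])
        assert clade.assigned_members == {"A", "F"}


class TestMeanPercentIdentity:
    def test_identical_rows_100(self):
        msa = Msa(ids=["a", "b"], rows=["MKV", "MKV"])
        assert mean_percent_identity(msa, ["a", "b"]) == 100.0

    def test_two_of_three_columns(self):
        msa = Msa(ids=["a", "b"], rows=["AAD", "AAE"])
        assert mean_percent_identity(msa, ["a", "b"]) == pytest.approx(200 / 3)

    def test_gap_columns_excluded_from_denominator(self):
        msa = Msa(ids=["a", "b"], rows=["A-C", "AGC"])
        assert mean_percent_identity(msa, ["a", "b"]) == 100.0

    def test_matches_brute_force_oracle(self, default_sim):
        msa = default_sim.truth.families[2].alignment
        members = msa.ids  # 30 rows
        fast = mean_percent_identity(msa, members)

        total, pairs = 0.0, 0
        for a, b in combinations(members, 2):
            ra, rb = msa.row(a), msa.row(b)
            same = used = 0
            for x, y in zip(ra, rb):
                if x != "-" and y != "-":
                    used += 1
                    same += x == y
            total += 100.0 * same / used
            pairs += 1
        assert fast == pytest.approx(total / pairs, abs=1e-12)

    def test_all_gap_column_insertion_invariant(self):
        msa = Msa(ids=["a", "b", "c"], rows=["MKVD", "MKLD", "MRVD"])
        padded = Msa(ids=["a", "b", "c"],
                     rows=["MK-VD", "MK-LD", "MR-VD"])
        assert mean_percent_identity(padded, msa.ids) == \
            pytest.approx(mean_percent_identity(msa, msa.ids))

    def test_row_order_invariant(self, default_sim):
        msa = default_sim.truth.families[0].alignment
        members = list(msa.ids)
        rng = random.Random(3)
        shuffled = members[:]
        rng.shuffle(shuffled)
        assert mean_percent_identity(msa, shuffled) == \
            pytest.approx(mean_percent_identity(msa, members), abs=1e-12)

    def test_disjoint_pair_raises_naming_pair(self):
        msa = Msa(ids=["a", "b"], rows=["AA--", "--CC"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            mean_percent_identity(msa, ["a", "b"])

    def test_fewer_than_two_members_raises(self):
        msa = Msa(ids=["a"], rows=["AA"])
        with pytest.raises(ValueError):
            mean_percent_identity(msa, ["a"])


class TestCladeProfile:
    def make_inputs(self):
        msa = Msa(ids=["a", "b", "c"], rows=["MKV", "MKV", "MRV"])
        annotations = {
            "a": AnnotationRow(id="a", phylum="Ascomycota", order="Eurotiales",
                               signal_flag=True, exon_count=1),
            "b": AnnotationRow(id="b", phylum="Ascomycota", order="Helotiales",
                               signal_flag=True, exon_count=1),
            "c": AnnotationRow(id="c", phylum="Basidiomycota", order="Agaricales",
                               signal_flag=None, exon_count=4),
        }
        clade = CladeDefinition(name="demo", reference_ids=("a",),
                                assigned_members={"a", "b", "c"})
        return msa, annotations, clade

    def test_signal_fraction_over_known_flags_only(self):
        msa, annotations, clade = self.make_inputs()
        profile = clade_profile(msa, annotations, clade)
        assert profile.signal_fraction == 1.0
        assert profile.effective_n["signal"] == 2

    def test_exon_aggregates(self):
        msa, annotations, clade = self.make_inputs()
        profile = clade_profile(msa, annotations, clade)
        assert profile.mean_exons == pytest.approx(2.0)
        assert profile.single_exon_fraction == pytest.approx(2 / 3)

    def test_taxonomy_tally(self):
        msa, annotations, clade = self.make_inputs()
        profile = clade_profile(msa, annotations, clade)
        assert profile.taxonomy_tally["phylum"] == \
            {"Ascomycota": 2, "Basidiomycota": 1}

    def test_single_member_clade_rejected(self):
        msa, annotations, _ = self.make_inputs()
        clade = CladeDefinition(name="one", reference_ids=("a",),
                                assigned_members={"a"})
        with pytest.raises(ValueError):
            clade_profile(msa, annotations, clade)


class TestNewickIO:
    def test_round_trip_preserves_labels_and_lengths(self, tmp_path):
        newick = "((A:1.5,B:2.25):0.5,C:3.125);"
        tree = read_newick(newick)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert patristic_distances(back) == patristic_distances(tree)
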