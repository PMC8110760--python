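"""Trimming, distances, NJ reconstruction, rooting, bootstraps, clan calls."""

import math

import numpy as np
import pytest

from cypome.formats import ProteinRecord, read_newick
from cypome.phylo_clan import (PhyloConfig, assign_clans, bootstrap_support,
                               distance_matrix, nj_tree, outgroup_root,
                               protein_distance, trim_columns)

from conftest import random_binary_tree, tree_distances


def _rec(name, seq):
    return ProteinRecord(name, seq)


class TestTrim:
    def test_majority_gap_column_removed(self):
        msa = [_rec("a", "AC-A"), _rec("b", "AC-A"), _rec("c", "AC-A"),
               _rec("d", "ACAA")]
        trimmed, removed = trim_columns(msa)
        assert removed == [2]
        assert all(r.residues == "ACA" for r in trimmed)

    def test_gap_free_alignment_unchanged(self):
        msa = [_rec("a", "ACDE"), _rec("b", "ACDF")]
        trimmed, removed = trim_columns(msa)
        assert removed == [] and [r.residues for r in trimmed] == ["ACDE", "ACDF"]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            trim_columns([_rec("a", "ACDE"), _rec("b", "ACD")])

    def test_row_emptied_by_trimming_warns(self):
        msa = [_rec("a", "A--"), _rec("b", "A--"), _rec("c", "-CC"),
               _rec("d", "-CC")]
        with pytest.warns(UserWarning):
            trimmed, removed = trim_columns(
                msa, PhyloConfig(trim_max_gap_fraction=0.4))
        assert removed == [0, 1, 2]


class TestDistance:
    def test_identical_rows_have_zero_distance(self):
        assert protein_distance("ACDE", "ACDE") == 0.0

    def test_kimura_formula_at_half_mismatch(self):
        # independent evaluation of d = -ln(1 - p - 0.2 p^2) at p = 0.5
        d = protein_distance("AAAA", "AACC")
        assert d == pytest.approx(-math.log(1 - 0.5 - 0.2 * 0.25))

    def test_saturated_pair_hits_cap(self):
        a = "A" * 100
        b = "C" * 85 + "A" * 15
        assert protein_distance(a, b) == 5.0

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError):
            protein_distance("A--", "-CC")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrix_recovers_generating_topology(self, n, rng):
        for _ in range(5):
            labels = [f"t{i}" for i in range(n)]
            truth = random_binary_tree(labels, rng)
            D, order = tree_distances(truth)
            est = nj_tree(D, order)
            assert est.bipartitions() == truth.bipartitions()

    def test_agrees_with_skbio_on_additive_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        labels = [f"t{i}" for i in range(6)]
        truth = random_binary_tree(labels, rng)
        D, order = tree_distances(truth)
        ours = nj_tree(D, order)
        theirs = skbio_nj(DistanceMatrix(D, order))
        their_bps = set()
        all_names = frozenset(order)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(order) - 1:
                their_bps.add(frozenset({side, all_names - side}))
        assert ours.bipartitions() == their_bps

    def test_equal_distances_resolve_deterministically(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(D, ["a", "b", "c", "d"])
        t2 = nj_tree(D, ["a", "b", "c", "d"])
        assert t1.newick() == t2.newick()


class TestRooting:
    def test_single_leaf_outgroup_roots_on_pendant_edge(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1,O:4);")
        rooted = outgroup_root(tree, {"O"})
        assert rooted.rooted and len(rooted.root.children) == 2
        sides = [c.leaf_names() for c in rooted.root.children]
        assert frozenset({"O"}) in sides

    def test_two_leaf_monophyletic_outgroup_roots_on_stem(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1,(O1:1,O2:1):3);")
        rooted = outgroup_root(tree, {"O1", "O2"})
        sides = [c.leaf_names() for c in rooted.root.children]
        assert frozenset({"O1", "O2"}) in sides

    def test_scattered_outgroup_warns_and_places_best_edge(self):
        tree = read_newick("((A:1,O1:1):1,(C:1,D:1):1,O2:4);")
        with pytest.warns(UserWarning, match="monophyletic"):
            rooted = outgroup_root(tree, {"O1", "O2"})
        assert rooted.rooted

    def test_rooting_preserves_leaf_path_lengths(self, rng):
        labels = [f"t{i}" for i in range(7)]
        truth = random_binary_tree(labels, rng)
        D0, order0 = tree_distances(truth)
        rooted = outgroup_root(truth, {"t0"})
        D1, order1 = tree_distances(rooted)
        idx = [order1.index(l) for l in order0]
        assert np.allclose(D0, D1[np.ix_(idx, idx)])


class TestBootstrap:
    def _alignment(self):
        # two well-separated clades with a long internal edge
        left = "AAAAAAAAAACCCCCCCCCC" * 5
        right = "TTTTTTTTTTGGGGGGGGGG" * 5
        def perturb(s, i):
            chars = list(s)
            chars[i] = "W"
            return "".join(chars)
        return [_rec("a1", left), _rec("a2", perturb(left, 0)),
                _rec("b1", right), _rec("b2", perturb(right, 1)),
                _rec("b3", perturb(right, 2))]

    def test_planted_split_gets_high_support(self):
        tree = bootstrap_support(self._alignment(),
                                 PhyloConfig(bootstrap_reps=50), seed=5)
        split = frozenset({frozenset({"a1", "a2"}),
                           frozenset({"b1", "b2", "b3"})})
        supports = {frozenset({n.leaf_names(),
                               tree.leaf_names() - n.leaf_names()}): n.support
                    for n in tree.root.traverse()
                    if not n.is_leaf and n is not tree.root}
        assert supports[split] >= 90

    def test_constant_alignment_of_identical_columns_gives_full_support(self):
        msa = [_rec("a", "AAAA"), _rec("b", "CCCC"), _rec("c", "GGGG"),
               _rec("d", "TTTT")]
        tree = bootstrap_support(msa, PhyloConfig(bootstrap_reps=20), seed=1)
        internal = [n for n in tree.root.traverse()
                    if not n.is_leaf and n is not tree.root]
        assert all(n.support == 100.0 for n in internal)

    def test_same_seed_reproduces_supports(self):
        msa = self._alignment()
        t1 = bootstrap_support(msa, PhyloConfig(bootstrap_reps=30), seed=9)
        t2 = bootstrap_support(msa, PhyloConfig(bootstrap_reps=30), seed=9)
        assert t1.newick() == t2.newick()


class TestAssignClans:
    def test_query_sister_to_single_reference(self):
        tree = read_newick("((Q:1,R2:1)95:1,(R3:1,O:1)90:1);")
        calls = assign_clans(tree, {"R2": "clan 2", "R3": "clan 3",
                                    "O": "outgroup"})
        call = {c.id: c for c in calls}["Q"]
        assert call.clan == "clan 2" and call.support == 95

    def test_query_basal_to_mixed_clans_is_unplaced(self):
        tree = read_newick(
            "((((A3:1,B3:1)99:1,(A4:1,B4:1)99:1)80:1,Q:1)90:1,O:4);")
        refs = {"A3": "clan 3", "B3": "clan 3", "A4": "clan 4",
                "B4": "clan 4", "O": "outgroup"}
        call = {c.id: c for c in assign_clans(tree, refs)}["Q"]
        assert call.clan == "unplaced"

    def test_unsupported_clade_is_skipped_not_used(self):
        # first informative clade has support 10: walk continues upward
        tree = read_newick("(((Q:1,R2:1)10:1,R2b:1)95:1,(R3:1,O:1)90:1);")
        refs = {"R2": "clan 2", "R2b": "clan 2", "R3": "clan 3",
                "O": "outgroup"}
        call = {c.id: c for c in assign_clans(tree, refs)}["Q"]
        assert call.clan == "clan 2"
        assert call.support == 95 and call.defining_clade_size == 3

    def test_tree_without_supports_warns_and_assigns(self):
        tree = read_newick("((Q:1,R2:1):1,(R3:1,O:1):1);")
        with pytest.warns(UserWarning, match="support"):
            calls = assign_clans(tree, {"R2": "clan 2", "R3": "clan 3",
                                        "O": "outgroup"})
        assert {c.id: c.clan for c in calls}["Q"] == "clan 2"

    def test_tree_without_references_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="reference"):
            assign_clans(tree, {})

    def test_assignment_invariant_to_leaf_rotation(self):
        t1 = read_newick("((Q:1,R2:1)95:1,(R3:1,O:1)90:1);")
        t2 = read_newick("((O:1,R3:1)90:1,(R2:1,Q:1)95:1);")
        refs = {"R2": "clan 2", "R3": "clan 3", "O": "outgroup"}
        c1 = {c.id: c.clan for c in assign_clans(t1, refs)}
        c2 = {c.id: c.clan for c in assign_clans(t2, refs)}
        assert c1 == c2
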