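import warnings

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfxkit import embedspace, treekit
from tfxkit.treekit import (DistanceMatrix, TreeError, distance_matrix,
                            is_monophyletic, neighbor_joining, p_distance,
                            random_additive_matrix, robinson_foulds)
from tfxkit.formats import SequenceRecord


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


class TestDistances:
    def test_identical_sequences_zero(self):
        assert p_distance("ACDE", "ACDE") == 0.0

    def test_one_mismatch_in_four(self):
        assert p_distance("ACDE", "ACDF") == 0.25

    def test_gap_column_excluded(self):
        # 5 columns, one gapped -> 4 comparable, 1 mismatch
        assert p_distance("AC-DE", "ACQDF") == 0.25

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from("ACDE-"), min_size=1, max_size=30),
           st.data())
    def test_p_distance_is_symmetric_and_bounded(self, a_chars, data):
        a = "".join(a_chars)
        b = "".join(data.draw(st.lists(st.sampled_from("ACDE-"),
                                       min_size=len(a), max_size=len(a))))
        comparable = any(x != "-" and y != "-" for x, y in zip(a, b))
        if not comparable:
            with pytest.raises(TreeError):
                p_distance(a, b)
            return
        d = p_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == p_distance(b, a)

    def test_ragged_alignment_rejected(self):
        records = [SequenceRecord("a", "ACDE"), SequenceRecord("b", "ACD")]
        with pytest.raises(TreeError, match="ragged"):
            distance_matrix(records, "p_distance_on_alignment")

    def test_feature_euclidean_matches_norm(self):
        mat = np.array([[0.0, 0.0], [3.0, 4.0]])
        dm = distance_matrix((["a", "b"], mat), "feature_euclidean")
        assert dm.values[0, 1] == pytest.approx(5.0)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(TreeError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(TreeError, match=">= 3"):
            neighbor_joining(dm)

    def test_three_leaf_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_quartet_recovers_ab_cd_split(self):
        vals = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                         [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), vals))
        assert is_monophyletic(tree, ["A", "B"])
        assert is_monophyletic(tree, ["C", "D"])

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_additive_matrices_recover_topology(self, n_leaves):
        for seed in range(10):
            dm, truth = random_additive_matrix(n_leaves, seed + 100 * n_leaves)
            assert robinson_foulds(neighbor_joining(dm), truth) == 0

    def test_negative_branches_clamped_with_warning(self):
        vals = np.array([[0, 1, 8, 8], [1, 0, 8, 8],
                         [8, 8, 0, 1], [8, 8, 1, 0]], float)
        vals[0, 1] = vals[1, 0] = 0.0
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), vals))
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length >= 0


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t1 = _tree("((a,b),(c,d));")
        t2 = _tree("((a,b),(c,d));")
        assert robinson_foulds(t1, t2) == 0

    def test_conflicting_quartets_distance_two(self):
        assert robinson_foulds(_tree("((a,b),(c,d));"),
                               _tree("((a,c),(b,d));")) == 2

    def test_caterpillar_distances_match_split_enumeration(self):
        t1 = _tree("(a,(b,(c,(d,e))));")
        # reading the same caterpillar backwards is the same unrooted tree
        assert robinson_foulds(t1, _tree("(e,(d,(c,(b,a))));")) == 0
        # swapping b and c changes one internal split ({cde} -> {bde})
        assert robinson_foulds(t1, _tree("(a,(c,(b,(d,e))));")) == 2

    def test_leaf_set_mismatch_lists_difference(self):
        with pytest.raises(TreeError, match="only in first.*'d'"):
            robinson_foulds(_tree("((a,b),(c,d));"), _tree("((a,b),(c,e));"))

    def test_metric_properties_on_sampled_triples(self):
        trees = [random_additive_matrix(7, s)[1] for s in range(6)]
        for t in trees:
            assert robinson_foulds(t, t) == 0
        for i in range(len(trees)):
            for j in range(i + 1, len(trees)):
                dij = robinson_foulds(trees[i], trees[j])
                assert dij == robinson_foulds(trees[j], trees[i])
                for k in range(len(trees)):
                    assert dij <= robinson_foulds(trees[i], trees[k]) + \
                        robinson_foulds(trees[k], trees[j])


class TestMonophyly:
    def test_full_leaf_set_trivially_true(self):
        t = _tree("((a,b),(c,d));")
        assert is_monophyletic(t, ["a", "b", "c", "d"])

    def test_single_leaf_trivially_true(self):
        assert is_monophyletic(_tree("((a,b),(c,d));"), ["c"])

    def test_split_pair_not_monophyletic(self):
        assert not is_monophyletic(_tree("((a,b),(c,d));"), ["a", "c"])

    def test_unknown_leaf_rejected(self):
        with pytest.raises(TreeError, match="unknown"):
            is_monophyletic(_tree("((a,b),(c,d));"), ["z"])

    def test_toxin_groups_monophyletic_in_descriptor_tree(self, clean_cohort):
        """Groups separated by framework descriptors (between-group
        divergence far exceeding within-group) form clades in the NJ tree."""
        sub = [t for t in clean_cohort.truth
               if t.group in {"ftx_short", "ftx_long", "ftx_plesiotypic"}
               and int(t.protein_id.rsplit("_", 1)[1]) < 10]
        seqs = {t.protein_id: t.mature_sequence for t in sub}
        ids, cys = embedspace.compose_features(seqs, "cys_descriptor")
        dm = distance_matrix((ids, embedspace.zscore(cys)), "feature_euclidean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = neighbor_joining(dm)
        for group in ("ftx_short", "ftx_long"):
            leaves = [t.protein_id for t in sub if t.group == group]
            assert is_monophyletic(tree, leaves)


class TestNJCrossCheck:
    def test_agrees_with_scikit_bio_on_additive_matrix(self):
        """Independent cross-check: scikit-bio's NJ recovers the same
        topology on an additive matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        dm, _ = random_additive_matrix(7, seed=5)
        mine = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.values, ids=list(dm.labels)))
        t2 = _tree(str(theirs).strip())
        assert robinson_foulds(mine, t2) == 0
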