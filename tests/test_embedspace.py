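import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfxkit import embedspace, reference
from tfxkit.embedspace import (EmbedError, ProjectionParams, composition20,
                               compose_features, concordance, dbscan, kmer2,
                               kmeans, optics_order, optics_xi, project)


class TestFeatures:
    def test_homopolymer_composition(self):
        v = composition20("AAAA")
        assert v[0] == 1.0 and v.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v) == 1

    @settings(derandomize=True, max_examples=60)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYXB*", min_size=1, max_size=80))
    def test_composition_always_sums_to_one(self, seq):
        if not any(a in "ACDEFGHIKLMNPQRSTVWY" for a in seq):
            with pytest.raises(EmbedError):
                composition20(seq)
        else:
            assert composition20(seq).sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimer_mode_single_nonzero_for_cc(self):
        v = kmer2("CC")
        assert np.count_nonzero(v) == 1
        ci = embedspace._AA_INDEX["C"]
        assert v[ci * 20 + ci] == 1.0

    def test_cys_descriptor_dimension(self, clean_cohort):
        t = clean_cohort.truth[0]
        assert embedspace.cys_descriptor(t.mature_sequence).shape == (16,)

    def test_imported_mode_joins_by_id(self):
        ids = ["b", "a"]
        mat = np.array([[1.0, 2.0], [3.0, 4.0]])
        out_ids, out = compose_features({"a": "MK", "b": "MR"}, "imported",
                                        imported=(ids, mat))
        assert out_ids == ["a", "b"]
        np.testing.assert_array_equal(out, [[3.0, 4.0], [1.0, 2.0]])

    def test_imported_mode_missing_id_listed(self):
        with pytest.raises(EmbedError, match="missing ids.*'b'"):
            compose_features({"a": "MK", "b": "MR"}, "imported",
                             imported=(["a"], np.zeros((1, 4))))

    def test_unknown_mode_rejected(self):
        with pytest.raises(EmbedError, match="unknown feature mode"):
            compose_features({"a": "MK"}, "pca")


class TestProjection:
    def test_too_few_points_rejected(self):
        params = ProjectionParams(n_neighbors=25)
        with pytest.raises(EmbedError, match="n_neighbors"):
            project(np.zeros((25, 4)), params)

    def test_deterministic_and_order_preserving(self, cohort_projection,
                                                diverged_cohort):
        ids, features, coords = cohort_projection
        assert coords.shape == (len(ids), 3)
        assert ids == [t.protein_id for t in diverged_cohort.truth]
        coords2 = project(features, ProjectionParams())
        np.testing.assert_array_equal(coords, coords2)

    def test_separated_blobs_stay_pure(self, cohort_projection,
                                       diverged_cohort):
        """Well-separated groups remain nearest-neighbour pure in 3D."""
        ids, _, coords = cohort_projection
        groups = [t.group for t in diverged_cohort.truth]
        assert embedspace.nearest_neighbor_purity(coords, groups) >= 0.99


class TestKmeans:
    def test_k_one_single_label(self):
        labels = kmeans(np.random.default_rng(0).normal(size=(10, 2)), 1)
        assert set(labels) == {0}

    def test_k_equals_n_singletons(self):
        pts = np.arange(10, dtype=float).reshape(5, 2)
        labels = kmeans(pts, 5, seed=0)
        assert len(set(labels)) == 5

    def test_seven_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        centers = rng.uniform(-50, 50, size=(7, 3))
        pts = np.vstack([c + rng.normal(0, 1.0, size=(20, 3)) for c in centers])
        truth = np.repeat(np.arange(7), 20)
        labels = kmeans(pts, 7, seed=0)
        assert concordance(labels, truth) == pytest.approx(1.0)

    def test_n_below_k_rejected(self):
        with pytest.raises(EmbedError, match="n >= k"):
            kmeans(np.zeros((3, 2)), 5)


class TestDbscan:
    def test_tight_cluster_plus_far_singleton(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.uniform(0, 0.1, size=(6, 2)), [[100.0, 100.0]]])
        labels = dbscan(pts, eps=0.55, min_pts=5)
        assert list(labels[:6]) == [0] * 6
        assert labels[6] == -1

    def test_identical_points_single_cluster(self):
        labels = dbscan(np.zeros((8, 3)), eps=0.55, min_pts=5)
        assert set(labels) == {0}

    def test_min_pts_above_n_all_noise(self):
        labels = dbscan(np.zeros((3, 2)), eps=0.55, min_pts=5)
        assert set(labels) == {-1}

    def test_matches_bruteforce_oracle_exhaustively(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 13))
            pts = rng.uniform(0, 3, size=(n, 2))
            for eps in (0.3, 0.55, 1.2):
                for mp in (2, 3, 5):
                    np.testing.assert_array_equal(
                        dbscan(pts, eps, mp),
                        reference.dbscan_bruteforce(pts, eps, mp),
                        err_msg=f"seed={seed} eps={eps} min_pts={mp}")


class TestOptics:
    def test_two_tight_blobs_two_leaf_clusters(self):
        pts = np.vstack([np.zeros((6, 2)), np.full((6, 2), 100.0)])
        res = optics_xi(pts, min_pts=2, xi=0.01)
        assert set(res.labels[:6]) == {0}
        assert set(res.labels[6:]) == {1}

    def test_single_uniform_blob_one_cluster(self):
        pts = np.zeros((10, 2))
        res = optics_xi(pts, min_pts=5, xi=0.01)
        assert set(res.labels) == {0}

    def test_n_equals_min_pts_identical_points(self):
        res = optics_xi(np.zeros((5, 2)), min_pts=5, xi=0.01)
        assert set(res.labels) == {0}

    def test_ordering_matches_bruteforce_oracle(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 13))
            pts = rng.uniform(0, 3, size=(n, 2))
            for mp in (2, 3, 5):
                if n < mp:
                    continue
                ordering, reach, core, _ = optics_order(pts, mp)
                o_ord, o_reach, o_core = reference.optics_order_bruteforce(pts, mp)
                assert list(ordering) == o_ord
                np.testing.assert_allclose(core, o_core)
                finite = np.isfinite(reach)
                np.testing.assert_allclose(reach[finite],
                                           np.array(o_reach)[finite])

    def test_too_few_points_rejected(self):
        with pytest.raises(EmbedError, match="min_pts"):
            optics_order(np.zeros((3, 2)), 5)


class TestConcordance:
    def test_identical_partitions(self):
        assert concordance([0, 0, 1, 1], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster_is_zero(self):
        # hand computation via the pair-counting contingency formula:
        # all pairs concordant by chance, ARI = 0
        assert concordance([0, 1, 2, 3], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_label_permutation_invariance(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [1, 1, 2, 0, 0, 2]
        remap = {0: 7, 1: 3, 2: 5}
        assert concordance(a, b) == pytest.approx(
            concordance([remap[x] for x in a], b))

    def test_symmetry(self):
        a, b = [0, 0, 1, 1, -1], [0, 1, 1, 1, 0]
        assert concordance(a, b) == pytest.approx(concordance(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(EmbedError, match="mismatch"):
            concordance([0, 1], [0, 1, 2])


class TestPipelineConcordance:
    def test_kmeans_seven_groups_high_ari(self, cohort_projection,
                                          diverged_cohort):
        """The seven generator groups are recovered by k-means (k=7) on the
        3D projection of composition + framework features."""
        ids, _, coords = cohort_projection
        truth = [t.group for t in diverged_cohort.truth]
        labels = kmeans(coords, 7, seed=0)
        assert concordance(labels, truth) >= 0.8

    def test_mad_split_recovered_by_classifier(self, diverged_cohort):
        """Anchored vs secreted separation: detect_mad calls agree with
        truth even on diverged sequences."""
        from tfxkit.cysclass import classify_protein
        from tfxkit.formats import SequenceRecord
        calls, truth = [], []
        for t in diverged_cohort.truth:
            _, _, call = classify_protein(SequenceRecord(t.protein_id, t.sequence))
            calls.append(call.secretion)
            truth.append(t.secretion)
        assert concordance(calls, truth) >= 0.9
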