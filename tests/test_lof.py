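"""LOF correctness: analytic geometry cases, brute-force oracle equivalence,
invariances, and agreement with an established library in novelty mode."""

import numpy as np
import pytest

from octanomaly.data import BinaryLabel
from octanomaly.lof import (
    LOF,
    LOFParams,
    ReferenceFeatureSet,
    calibrate_threshold,
    k_distance,
    k_neighborhood,
    lof_score,
    lrd,
    reach_dist,
    score_queries,
)
from oracles import brute_fit_scores, brute_k_distance, brute_lof, brute_neighborhood

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


class TestKDistance:
    def test_points_on_a_line(self):
        refs = ReferenceFeatureSet(np.array([[1.0], [2.0], [3.0]]))
        assert k_distance(np.array([0.0]), refs, k=2) == pytest.approx(2.0)

    def test_square_corner_with_ties(self):
        refs = ReferenceFeatureSet(SQUARE[1:])  # the other three corners
        assert k_distance(SQUARE[0], refs, k=2) == pytest.approx(1.0)

    def test_k_too_large_is_parameter_error(self):
        refs = ReferenceFeatureSet(SQUARE)
        with pytest.raises(ValueError):
            k_distance(np.zeros(2), refs, k=5)

    def test_matches_brute_force_for_all_k(self, rng):
        pts = rng.normal(size=(50, 2))
        refs = ReferenceFeatureSet(pts)
        o = rng.normal(size=2)
        for k in range(1, 11):
            assert k_distance(o, refs, k) == pytest.approx(
                brute_k_distance(o, pts, k), rel=1e-12
            )


class TestKNeighborhood:
    def test_square_corner_excludes_diagonal(self):
        refs = ReferenceFeatureSet(SQUARE[1:])
        nb = k_neighborhood(SQUARE[0], refs, k=2)
        # adjacent corners (distance 1) in, diagonal (sqrt 2) out
        assert sorted(nb) == [0, 1]

    def test_tie_inclusion_grows_neighborhood(self):
        refs = ReferenceFeatureSet(np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]]))
        nb = k_neighborhood(np.zeros(2), refs, k=2)
        assert len(nb) == 3  # all three refs are at distance 1

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(40, 3))
        refs = ReferenceFeatureSet(pts)
        for _ in range(10):
            o = rng.normal(size=3)
            k = int(rng.integers(1, 9))
            assert sorted(k_neighborhood(o, refs, k)) == brute_neighborhood(o, pts, k)


class TestReachDist:
    def test_far_branch_takes_true_distance(self):
        refs = ReferenceFeatureSet(SQUARE)
        # E=(5,5) to corner (1,1): d = sqrt(32) > k-distance((1,1)) = 1
        assert reach_dist(np.array([5.0, 5.0]), 3, refs, k=2) == pytest.approx(np.sqrt(32))

    def test_smoothing_branch_takes_k_distance(self):
        refs = ReferenceFeatureSet(SQUARE)
        p = np.array([0.9, 0.9])  # 0.141... from (1,1), below its k-distance 1
        assert reach_dist(p, 3, refs, k=2) == pytest.approx(1.0)

    def test_reach_dist_at_least_distance(self, rng):
        pts = rng.normal(size=(20, 2))
        refs = ReferenceFeatureSet(pts)
        for _ in range(20):
            p = rng.normal(size=2)
            i = int(rng.integers(0, 20))
            rd = reach_dist(p, i, refs, k=3)
            assert rd >= np.linalg.norm(p - pts[i]) - 1e-12


class TestLrdAndScore:
    def test_square_fit_mode_lrd_all_one(self):
        model = LOF(k=2).fit(SQUARE)
        np.testing.assert_allclose(model.ref_lrd, 1.0, rtol=1e-12)

    def test_external_query_lrd_hand_value(self):
        # E=(5,5): neighborhood = {(1,1),(1,0),(0,1)} with a distance tie,
        # reach-dists are the true distances, so lrd = 3/(sqrt32+sqrt41+sqrt41)
        refs = ReferenceFeatureSet(SQUARE)
        expected = 3.0 / (np.sqrt(32) + 2 * np.sqrt(41))
        assert lrd(np.array([5.0, 5.0]), refs, k=2) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1625, abs=5e-4)

    def test_duplicated_point_gets_infinite_lrd(self):
        refs = ReferenceFeatureSet(np.vstack([np.zeros((4, 2)), SQUARE + 5.0]))
        assert lrd(np.zeros(2), refs, k=3) == np.inf

    def test_square_symmetry_gives_lof_one(self):
        scores = LOF(k=2).fit(SQUARE).fit_scores()
        np.testing.assert_allclose(scores, 1.0, rtol=1e-12)

    def test_far_query_hand_value(self):
        refs = ReferenceFeatureSet(SQUARE)
        expected = (np.sqrt(32) + 2 * np.sqrt(41)) / 3.0  # neighbor lrds are all 1
        got = lof_score(np.array([5.0, 5.0]), refs, k=2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(6.154, abs=1e-3)

    def test_duplicate_cluster_scores_one_infinity_convention(self):
        # query duplicating a k+1-fold repeated reference point: inf/inf := 1
        refs = ReferenceFeatureSet(np.vstack([np.zeros((4, 2)), SQUARE + 5.0]))
        assert lof_score(np.zeros(2), refs, k=3) == pytest.approx(1.0)

    def test_planted_outlier_has_max_score(self, rng):
        hits = 0
        for trial in range(100):
            r = np.random.default_rng(1000 + trial)
            pts = r.normal(size=(100, 3))
            outlier = np.full(3, 12.0)
            model = LOF(k=10).fit(np.vstack([pts, outlier]))
            hits += int(np.argmax(model.fit_scores()) == 100)
        assert hits >= 99


class TestOracleEquivalence:
    def test_random_instances_match_brute_force_everywhere(self):
        """Every intermediate (k-distance, neighborhood, reach-dist, lrd, LOF)
        matches the literal implementation, fit and novelty modes, with ties
        and duplicates present."""
        master = np.random.default_rng(424242)
        for trial in range(40):
            n = int(master.integers(8, 30))
            d = int(master.integers(1, 5))
            k = int(master.integers(1, min(8, n - 1) + 1))
            pts = np.round(master.normal(size=(n, d)), 1)  # rounding induces ties/dups
            refs = ReferenceFeatureSet(pts)
            model = LOF(k=k).fit(pts)
            np.testing.assert_allclose(
                model.fit_scores(), brute_fit_scores(pts.tolist(), k), rtol=1e-9
            )
            for _ in range(3):
                q = np.round(master.normal(size=d), 1)
                assert k_distance(q, refs, k) == pytest.approx(
                    brute_k_distance(q, pts.tolist(), k), rel=1e-9
                )
                assert sorted(k_neighborhood(q, refs, k)) == brute_neighborhood(
                    q, pts.tolist(), k
                )
                got = lof_score(q, refs, k)
                want = brute_lof(q, pts.tolist(), k)
                if np.isinf(want):
                    assert np.isinf(got)
                else:
                    assert got == pytest.approx(want, rel=1e-9)


class TestInvariances:
    def test_rigid_motion_leaves_scores_unchanged(self, rng):
        pts = rng.normal(size=(40, 2))
        queries = rng.normal(size=(10, 2))
        theta = 0.73
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([3.0, -7.0])
        base = LOF(k=5).fit(pts).score_samples(queries)
        moved = LOF(k=5).fit(pts @ R.T + shift).score_samples(queries @ R.T + shift)
        np.testing.assert_allclose(base, moved, rtol=1e-9)

    def test_score_monotone_in_radial_distance(self, rng):
        pts = rng.normal(size=(60, 2))
        model = LOF(k=8).fit(pts)
        centroid = pts.mean(axis=0)
        direction = np.array([1.0, 0.5]) / np.linalg.norm([1.0, 0.5])
        radius0 = np.max(np.linalg.norm(pts - centroid, axis=1)) + np.max(model.kdist)
        radii = radius0 + np.linspace(0, 30, 12)
        scores = model.score_samples(centroid + radii[:, None] * direction)
        assert np.all(np.diff(scores) >= -1e-9)

    def test_query_order_independence(self, rng):
        pts = rng.normal(size=(50, 4))
        queries = rng.normal(size=(12, 4))
        refs = ReferenceFeatureSet(pts)
        params = LOFParams(k=7, threshold=1.5)
        fwd = score_queries(queries, refs, params)
        perm = np.array([5, 2, 9, 0, 11, 3, 7, 1, 10, 4, 8, 6])
        bwd = score_queries(queries[perm], refs, params)
        for i, j in enumerate(perm):
            assert bwd[i].score == pytest.approx(fwd[j].score, rel=1e-12)
            assert bwd[i].decision == fwd[j].decision

    def test_cosine_and_euclidean_rank_identically_on_sphere(self, rng):
        pts = rng.normal(size=(50, 5))
        pts = 5.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        q = rng.normal(size=(1, 5))
        q = 5.0 * q / np.linalg.norm(q)
        for k in (3, 7):
            nb_e = sorted(k_neighborhood(q[0], ReferenceFeatureSet(pts, "euclidean"), k))
            nb_c = sorted(k_neighborhood(q[0], ReferenceFeatureSet(pts, "cosine"), k))
            assert nb_e == nb_c


class TestAgainstReferenceLibrary:
    def test_novelty_scores_match_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.neighbors")
        for trial in range(10):
            r = np.random.default_rng(7000 + trial)
            pts = r.normal(size=(60, 4))
            queries = r.normal(size=(15, 4)) * 2.0
            k = int(r.integers(2, 12))
            ours = LOF(k=k).fit(pts).score_samples(queries)
            ref = sklearn.LocalOutlierFactor(n_neighbors=k, novelty=True).fit(pts)
            theirs = -ref.score_samples(queries)  # sklearn negates LOF
            np.testing.assert_allclose(ours, theirs, rtol=1e-6)

    def test_fit_scores_match_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.neighbors")
        pts = rng.normal(size=(80, 3))
        ours = LOF(k=10).fit(pts).fit_scores()
        ref = sklearn.LocalOutlierFactor(n_neighbors=10).fit(pts)
        np.testing.assert_allclose(ours, -ref.negative_outlier_factor_, rtol=1e-6)


class TestDecisions:
    def test_on_manifold_query_is_normal_at_fixed_threshold(self, rng):
        pts = rng.uniform(size=(200, 2))
        refs = ReferenceFeatureSet(pts)
        results = score_queries(pts[0][None], refs, LOFParams(k=10, threshold=1.5))
        assert results[0].score == pytest.approx(1.0, abs=0.3)
        assert results[0].decision is BinaryLabel.NORMAL

    def test_far_outlier_is_amd_at_fixed_threshold(self):
        refs = ReferenceFeatureSet(SQUARE)
        results = score_queries(np.array([[5.0, 5.0]]), refs, LOFParams(k=2, threshold=1.5))
        assert results[0].decision is BinaryLabel.AMD

    def test_auto_threshold_is_quantile_of_fit_scores(self, rng):
        pts = rng.normal(size=(100, 3))
        refs = ReferenceFeatureSet(pts)
        params = LOFParams(k=10, threshold="auto", quantile=0.9)
        tau = calibrate_threshold(refs, params)
        scores = LOF(k=10).fit(pts).fit_scores()
        assert tau == pytest.approx(np.quantile(scores, 0.9))

    def test_dimension_mismatch_rejected(self, rng):
        refs = ReferenceFeatureSet(rng.normal(size=(30, 3)))
        with pytest.raises(ValueError):
            score_queries(rng.normal(size=(2, 4)), refs, LOFParams(k=3, threshold=1.5))

    def test_k_not_smaller_than_reference_rejected(self):
        refs = ReferenceFeatureSet(SQUARE)
        with pytest.raises(ValueError):
            score_queries(np.zeros((1, 2)), refs, LOFParams(k=4, threshold=1.5))
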