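import numpy as np
import pytest
from scipy.stats import multivariate_normal

import pcareduce as pr
from pcareduce import (
    InvalidParameterError,
    MergeCandidate,
    StaleCandidateError,
    apply_merge,
    compute_scores,
    initialise,
    merge_log_score,
    pooled_moments,
    score_all_pairs,
    select_merge,
)
from pcareduce.hierarchy import state_from_assignment


class TestPooledMoments:
    @pytest.mark.parametrize(
        "size_i, mean_i, size_j, mean_j, expected_mean",
        [
            (3, (0.0, 0.0), 1, (4.0, 0.0), (1.0, 0.0)),
            (1, (2.0, 2.0), 1, (2.0, 2.0), (2.0, 2.0)),
            (5, (1.0, -1.0), 5, (3.0, 1.0), (2.0, 0.0)),
        ],
    )
    def test_weighted_mean(self, size_i, mean_i, size_j, mean_j, expected_mean):
        eye = np.eye(2)
        mean, _ = pooled_moments(size_i, np.array(mean_i), eye,
                                 size_j, np.array(mean_j), eye)
        assert np.array_equal(mean, expected_mean)

    def test_equal_weight_covariance_average(self):
        _, cov = pooled_moments(4, np.zeros(3), np.eye(3),
                                4, np.zeros(3), 3 * np.eye(3))
        assert np.array_equal(cov, 2 * np.eye(3))

    def test_equal_moments_are_fixed_point(self):
        m, S = np.array([1.0, 2.0]), np.array([[2.0, 0.5], [0.5, 1.0]])
        mean, cov = pooled_moments(7, m, S, 2, m, S)
        assert np.allclose(mean, m) and np.allclose(cov, S)

    def test_pooled_mean_is_convex_combination(self):
        rng = np.random.default_rng(0)
        mi, mj = rng.normal(size=3), rng.normal(size=3)
        mean, _ = pooled_moments(3, mi, np.eye(3), 9, mj, np.eye(3))
        # mean - mj is parallel to mi - mj with a coefficient in [0, 1]
        coeff = (mean - mj) / (mi - mj)
        assert np.allclose(coeff, coeff[0]) and 0 <= coeff[0] <= 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(pr.InvalidInputError):
            pooled_moments(1, np.zeros(2), np.eye(2), 1, np.zeros(3), np.eye(3))


class TestMergeLogScore:
    def test_point_at_mode_of_standard_gaussian(self):
        mean = np.array([1.5, -2.0])
        score = merge_log_score(mean[None, :], mean, np.eye(2))
        assert np.isclose(score, -np.log(2 * np.pi))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        members = rng.normal(size=(8, 3))
        mean = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        shift = rng.normal(size=3) * 100
        s1 = merge_log_score(members, mean, cov)
        s2 = merge_log_score(members + shift, mean + shift, cov)
        assert np.isclose(s1, s2)

    def test_matches_per_point_density_product(self):
        rng = np.random.default_rng(2)
        members = rng.normal(size=(10, 3))
        mean = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 0.2 * np.eye(3)
        expected = multivariate_normal(mean, cov).logpdf(members).sum()
        assert abs(merge_log_score(members, mean, cov) - expected) < 1e-8

    def test_mean_mode_divides_by_member_count(self):
        rng = np.random.default_rng(3)
        members = rng.normal(size=(6, 2))
        joint = merge_log_score(members, np.zeros(2), np.eye(2), mode="joint")
        mean = merge_log_score(members, np.zeros(2), np.eye(2), mode="mean")
        assert np.isclose(mean, joint / 6)

    def test_degenerate_covariance_raises(self):
        with pytest.raises(pr.NumericalDegeneracyError):
            merge_log_score(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)))

    def test_ridge_restores_invertibility(self):
        score = merge_log_score(np.zeros((2, 2)), np.zeros(2),
                                np.zeros((2, 2)), ridge=1e-6)
        assert np.isfinite(score)


class TestInitialise:
    def test_separated_groups_recovered_exactly(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)),
                         rng.normal(100, 0.1, (10, 2))])
        Y = pr.ScoreMatrix(pts - pts.mean(axis=0),
                           np.sort(pts.var(axis=0, ddof=1))[::-1])
        state = initialise(Y, 2, seed=0)
        assert len(set(state.assignment[:10])) == 1
        assert len(set(state.assignment[10:])) == 1
        assert state.assignment[0] != state.assignment[-1]

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        Y = compute_scores(pr.ExpressionMatrix(pts), 2)
        state = initialise(Y, 6, seed=0)
        assert np.array_equal(np.sort(state.sizes), np.ones(6))
        for i in range(6):
            member = Y.scores[state.assignment == i][0]
            assert np.allclose(state.centroids[i], member)
            assert np.allclose(state.covariances[i], 0.0)

    def test_k_larger_than_n_rejected(self):
        Y = compute_scores(pr.ExpressionMatrix(np.random.default_rng(6).normal(size=(5, 3))), 2)
        with pytest.raises(InvalidParameterError):
            initialise(Y, 6, seed=0)

    def test_centroids_match_member_means(self):
        rng = np.random.default_rng(7)
        Y = compute_scores(pr.ExpressionMatrix(rng.normal(size=(40, 8))), 4)
        state = initialise(Y, 5, seed=1)
        assert state.sizes.sum() == 40
        for i in range(5):
            rows = Y.scores[state.assignment == i]
            assert np.allclose(state.centroids[i], rows.mean(axis=0))
            # ML covariance, symmetric PSD
            assert np.allclose(state.covariances[i], state.covariances[i].T)
            assert np.linalg.eigvalsh(state.covariances[i]).min() >= -1e-10


class TestScoreAllPairs:
    @pytest.mark.parametrize("k, expected", [(2, 1), (5, 10)])
    def test_candidate_count(self, k, expected):
        rng = np.random.default_rng(8)
        Y = compute_scores(pr.ExpressionMatrix(rng.normal(size=(4 * k, 6))), 3)
        state = state_from_assignment(Y, np.repeat(np.arange(k), 4))
        assert len(score_all_pairs(state, Y)) == expected

    def test_label_order_does_not_change_score_multiset(self):
        rng = np.random.default_rng(9)
        Y = compute_scores(pr.ExpressionMatrix(rng.normal(size=(24, 6))), 3)
        labels = np.repeat(np.arange(4), 6)
        shuffled = np.array([2, 0, 3, 1])[labels]  # same partition, new names
        s1 = sorted(c.log_score for c in score_all_pairs(state_from_assignment(Y, labels), Y))
        s2 = sorted(c.log_score for c in score_all_pairs(state_from_assignment(Y, shuffled), Y))
        assert np.allclose(s1, s2)


class TestSelectMerge:
    def _candidates(self, log_scores):
        return [
            MergeCandidate(pair=(0, i + 1), pooled_mean=np.zeros(1),
                           pooled_cov=np.eye(1), log_score=s,
                           k_at_scoring=len(log_scores) + 1)
            for i, s in enumerate(log_scores)
        ]

    def test_single_candidate_chosen_by_either_strategy(self):
        cands = self._candidates([-2.0])
        rng = np.random.default_rng(0)
        assert select_merge(cands, "max") is cands[0]
        assert select_merge(cands, "sample", rng) is cands[0]

    def test_max_picks_argmax(self):
        cands = self._candidates([-5.0, -1.0, -9.0])
        assert select_merge(cands, "max") is cands[1]

    def test_max_ties_broken_by_smallest_pair(self):
        cands = self._candidates([-1.0, -1.0, -3.0])
        assert select_merge(cands, "max") is cands[0]

    def test_sampling_frequency_matches_normalised_weights(self):
        # weights 1 : 3, so the second candidate should appear ~75 % of draws
        cands = self._candidates([np.log(1.0), np.log(3.0)])
        rng = np.random.default_rng(10)
        draws = sum(select_merge(cands, "sample", rng) is cands[1]
                    for _ in range(10_000))
        se = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(draws / 10_000 - 0.75) < 3 * se

    def test_empty_candidates_rejected(self):
        with pytest.raises(pr.InvalidInputError):
            select_merge([], "max")


class TestApplyMerge:
    def _setup(self, seed=11, n=30, k=3, q=4):
        rng = np.random.default_rng(seed)
        Y = compute_scores(pr.ExpressionMatrix(rng.normal(size=(n, 8))), q)
        state = state_from_assignment(Y, rng.integers(0, k, size=n))
        return state, Y

    def test_membership_conserved_and_sizes_add(self):
        state, Y = self._setup()
        cands = score_all_pairs(state, Y)
        chosen = select_merge(cands, "max")
        i, j = chosen.pair
        before = (state.sizes[i], state.sizes[j], state.sizes.sum())
        new_state, new_Y = apply_merge(state, chosen, Y)
        assert new_state.k == state.k - 1
        assert new_state.sizes.sum() == before[2]
        assert before[0] + before[1] in new_state.sizes
        assert new_Y.q == Y.q - 1
        assert new_state.q_cur == new_Y.q

    def test_final_merge_collapses_to_one_cluster_without_dim_drop(self):
        state, Y = self._setup(k=2, q=1)
        chosen = select_merge(score_all_pairs(state, Y), "max")
        new_state, new_Y = apply_merge(state, chosen, Y)
        assert new_state.k == 1
        assert new_state.sizes[0] == state.n
        assert new_Y.q == 1  # no drop below one dimension

    def test_merged_moments_are_pooled_moments_restricted(self):
        state, Y = self._setup()
        chosen = select_merge(score_all_pairs(state, Y), "max")
        new_state, _ = apply_merge(state, chosen, Y)
        i = chosen.pair[0]
        assert np.allclose(new_state.centroids[i], chosen.pooled_mean[:-1])
        assert np.allclose(new_state.covariances[i], chosen.pooled_cov[:-1, :-1])

    def test_stale_candidate_rejected(self):
        state, Y = self._setup()
        chosen = select_merge(score_all_pairs(state, Y), "max")
        new_state, new_Y = apply_merge(state, chosen, Y)
        with pytest.raises(StaleCandidateError):
            apply_merge(new_state, chosen, new_Y)


class TestRun:
    def test_levels_and_loop_structure(self, two_blobs):
        X, _ = two_blobs
        h = pr.run(X, k_init=6, strategy="max", seed=0)
        assert sorted(h.levels) == list(range(1, 7))
        for k, labels in h.levels.items():
            assert len(np.unique(labels)) == k
        assert np.array_equal(h.levels[1], np.ones(X.n_cells, dtype=int))

    def test_dimension_schedule(self, two_blobs):
        # working dimension when scoring at k clusters is always k - 1
        X, _ = two_blobs
        h = pr.run(X, k_init=6, strategy="max", seed=0)
        for rec in h.merge_trace:
            assert rec["dim"] == rec["level"] - 1

    def test_nesting_between_levels(self, two_blobs):
        X, _ = two_blobs
        h = pr.run(X, k_init=6, strategy="sample", seed=1)
        for k in range(2, 7):
            fine, coarse = h.levels[k], h.levels[k - 1]
            # each finer cluster maps into exactly one coarser cluster
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c
            assert len(set(mapping.keys())) - len(set(mapping.values())) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_separated_blobs_recovered_at_two_cluster_level(self, two_blobs, seed):
        X, truth = two_blobs
        h = pr.run(X, k_init=6, strategy="max", seed=seed)
        assert pr.adjusted_rand_index(h.levels[2], truth) == 1.0

    def test_same_seed_identical_hierarchy(self, two_blobs):
        X, _ = two_blobs
        h1 = pr.run(X, k_init=5, strategy="sample", seed=42)
        h2 = pr.run(X, k_init=5, strategy="sample", seed=42)
        assert h1.merge_trace == h2.merge_trace
        assert all(np.array_equal(h1.levels[k], h2.levels[k]) for k in h1.levels)

    def test_sign_flip_of_scores_leaves_merge_scores_unchanged(self, two_blobs):
        # flipping a score column is an isometry of every Gaussian involved
        X, _ = two_blobs
        Y = pr.compute_scores(X, 3)
        state = state_from_assignment(Y, np.random.default_rng(2).integers(0, 3, X.n_cells))
        flipped = pr.ScoreMatrix(Y.scores * np.array([1, -1, 1]), Y.explained_variance)
        state_f = state_from_assignment(flipped, state.assignment)
        s1 = [c.log_score for c in score_all_pairs(state, Y)]
        s2 = [c.log_score for c in score_all_pairs(state_f, flipped)]
        assert np.allclose(s1, s2)

    def test_permutation_equivariance_with_injected_init(self, two_blobs):
        X, _ = two_blobs
        rng = np.random.default_rng(3)
        init = rng.integers(0, 4, X.n_cells)
        while len(np.unique(init)) < 4:  # ensure 4 non-empty clusters
            init = rng.integers(0, 4, X.n_cells)
        perm = rng.permutation(X.n_cells)
        h1 = pr.run(X, 4, "max", seed=0, initial_assignment=init)
        Xp = pr.ExpressionMatrix(X.values[perm])
        h2 = pr.run(Xp, 4, "max", seed=0, initial_assignment=init[perm])
        for k in h1.levels:
            assert pr.adjusted_rand_index(h1.levels[k][perm], h2.levels[k]) == 1.0

    def test_invalid_k_init_rejected(self, two_blobs):
        X, _ = two_blobs
        for bad in (1, X.n_cells + 1):
            with pytest.raises(InvalidParameterError):
                pr.run(X, k_init=bad, strategy="max", seed=0)

    def test_mean_score_mode_runs(self, two_blobs):
        X, truth = two_blobs
        h = pr.run(X, 6, "max", seed=0, score_mode="mean")
        assert pr.adjusted_rand_index(h.levels[2], truth) == 1.0


class TestRunEnsemble:
    def test_reproducible_from_master_seed(self, two_blobs):
        X, _ = two_blobs
        e1 = pr.run_ensemble(X, 5, n_runs=3, seed=9)
        e2 = pr.run_ensemble(X, 5, n_runs=3, seed=9)
        for h1, h2 in zip(e1, e2):
            assert h1.seed == h2.seed
            assert all(np.array_equal(h1.levels[k], h2.levels[k]) for k in h1.levels)

    def test_single_run_ensemble_matches_direct_run(self, two_blobs):
        X, _ = two_blobs
        (h1,) = pr.run_ensemble(X, 5, n_runs=1, seed=9)
        h2 = pr.run(X, 5, "sample", seed=h1.seed)
        assert all(np.array_equal(h1.levels[k], h2.levels[k]) for k in h1.levels)

    def test_runs_use_distinct_sub_seeds(self, two_blobs):
        X, _ = two_blobs
        ensemble = pr.run_ensemble(X, 5, n_runs=4, seed=0)
        assert len({h.seed for h in ensemble}) == 4
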