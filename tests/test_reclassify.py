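"""Soft clustering, the balanced separation cost, and feature selection."""

import numpy as np
import pandas as pd
import pytest

from meningrade.reclassify import (
    FeatureSet,
    backward_eliminate,
    cluster_polarity,
    fcm_cluster,
    forward_select,
    grade3_membership,
    reclassify_grade2,
    select_signature,
    separation_cost,
)


def feature_set(matrix: np.ndarray, names=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] == 1:
        matrix = matrix.T
    names = names or [f"f{i}" for i in range(matrix.shape[1])]
    samples = [f"S{i}" for i in range(matrix.shape[0])]
    return FeatureSet(
        feature_ids=tuple(names),
        matrix=pd.DataFrame(matrix, index=samples, columns=names),
    )


def fcm_reference(X, m=2.0, tol=1e-10, max_iter=2000, U0=None):
    """Independent, loop-based evaluation of the FCM update equations."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n, _ = X.shape
    c = 2
    U = U0.copy()
    for _ in range(max_iter):
        centroids = []
        for j in range(c):
            w = U[:, j] ** m
            centroids.append((w[:, None] * X).sum(axis=0) / w.sum())
        U_new = np.zeros_like(U)
        for k in range(n):
            d = [np.linalg.norm(X[k] - centroids[j]) for j in range(c)]
            if min(d) < 1e-12:
                for j in range(c):
                    U_new[k, j] = 1.0 if d[j] < 1e-12 else 0.0
                U_new[k] /= U_new[k].sum()
                continue
            for j in range(c):
                U_new[k, j] = 1.0 / sum(
                    (d[j] / d[l]) ** (2.0 / (m - 1.0)) for l in range(c)
                )
        if np.abs(U_new - U).max() < tol:
            U = U_new
            break
        U = U_new
    return U, np.array(centroids)


class TestFCM:
    def test_well_separated_clouds_get_confident_memberships(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-5, 0.1, 20), rng.normal(5, 0.1, 20)])
        res = fcm_cluster(feature_set(x), seed=1)
        U = res.membership.to_numpy()
        assert (U.max(axis=1) > 0.99).all()
        # the two clouds land in different clusters
        assert U[:20].argmax(axis=1).std() == 0
        assert U[:20, 0].mean() != pytest.approx(U[20:, 0].mean(), abs=0.5)

    def test_midpoint_sample_has_half_membership(self):
        x = np.array([-1.0, -1.0, -1.0, 0.0, 1.0, 1.0, 1.0])
        res = fcm_cluster(feature_set(x), seed=0)
        mid = res.membership.iloc[3]
        assert mid[0] == pytest.approx(0.5, abs=1e-3)
        assert mid[1] == pytest.approx(0.5, abs=1e-3)

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = fcm_cluster(feature_set(rng.normal(size=(30, 3))), seed=0)
        np.testing.assert_allclose(res.membership.sum(axis=1).to_numpy(), 1.0)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        res = fcm_cluster(feature_set(rng.normal(size=(40, 2))), seed=5, n_restarts=1)
        trace = np.array(res.objective_trace)
        assert (np.diff(trace) <= 1e-10).all()

    def test_matches_independent_reference_in_1d(self):
        """Oracle equivalence on small 1-D instances."""
        rng = np.random.default_rng(11)
        for n in (4, 6, 8):
            x = rng.normal(size=n) * 2
            fs = feature_set(x)
            res = fcm_cluster(fs, seed=7, n_restarts=1, tol=1e-12, max_iter=2000)
            # re-run the reference from the same converged point: a fixed
            # point of our updates must be a fixed point of the reference
            U_ref, _ = fcm_reference(x, U0=res.membership.to_numpy())
            cols = [0, 1]
            if not np.allclose(U_ref[:, 0], res.membership[0], atol=1e-6):
                cols = [1, 0]
            np.testing.assert_allclose(
                U_ref[:, cols], res.membership.to_numpy(), atol=1e-6
            )

    def test_coincident_sample_gets_hard_membership(self):
        x = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        res = fcm_cluster(feature_set(x), seed=0)
        assert res.membership.to_numpy().max() > 0.999

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(4)
        fs = feature_set(rng.normal(size=(25, 2)))
        a = fcm_cluster(fs, seed=9)
        b = fcm_cluster(fs, seed=9)
        pd.testing.assert_frame_equal(a.membership, b.membership)

    def test_invalid_fuzzifier_rejected(self):
        with pytest.raises(ValueError, match="fuzzifier"):
            fcm_cluster(feature_set(np.arange(5.0)), fuzzifier=1.0)


def _graded(n1=6, n2=4, n3=6):
    grades = pd.Series(
        [1] * n1 + [2] * n2 + [3] * n3,
        index=[f"S{i}" for i in range(n1 + n2 + n3)],
    )
    return grades


class TestClusterPolarity:
    def _result(self, u0):
        u0 = np.asarray(u0, dtype=float)
        U = np.column_stack([u0, 1 - u0])
        from meningrade.reclassify import MembershipResult

        return MembershipResult(
            membership=pd.DataFrame(
                U, index=[f"S{i}" for i in range(len(u0))], columns=[0, 1]
            ),
            centroids=np.zeros((2, 1)),
            fuzzifier=2.0,
            objective=0.0,
            n_iter=1,
            converged=True,
        )

    def test_grade3_heavy_tail_sets_polarity(self):
        # grade 1 samples near cluster 0, grade 3 near cluster 1
        u0 = [0.95] * 6 + [0.5] * 4 + [0.05] * 6
        res = cluster_polarity(self._result(u0), _graded())
        assert res.grade3_cluster == 1
        p = grade3_membership(res)
        assert p.iloc[0] == pytest.approx(0.05)

    def test_flipping_memberships_flips_polarity_not_p(self):
        u0 = np.array([0.95] * 6 + [0.5] * 4 + [0.05] * 6)
        res = cluster_polarity(self._result(u0), _graded())
        flipped = cluster_polarity(self._result(1 - u0), _graded())
        assert flipped.grade3_cluster == 1 - res.grade3_cluster
        np.testing.assert_allclose(
            grade3_membership(res).to_numpy(),
            grade3_membership(flipped).to_numpy(),
            atol=1e-12,
        )

    def test_empty_tails_fall_back_to_medians_with_warning(self):
        u0 = [0.6] * 6 + [0.5] * 4 + [0.4] * 6  # nobody reaches 0.8
        with pytest.warns(UserWarning, match="polarity"):
            res = cluster_polarity(self._result(u0), _graded())
        assert res.grade3_cluster == 1  # grade 3 median membership higher there

    def test_polarity_matches_planted_truth_across_seeds(self):
        """Two shifted Gaussians labelled 1/3: the grade-3-enriched cluster
        must be the one holding the grade-3 cloud."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(-2, 0.5, 20), rng.normal(2, 0.5, 15)])
            grades = pd.Series([1] * 20 + [3] * 15, index=[f"S{i}" for i in range(35)])
            res = fcm_cluster(feature_set(x), seed=seed)
            res = cluster_polarity(res, grades)
            p = grade3_membership(res)
            hits += int(p.iloc[-1] > 0.5 and p.iloc[0] < 0.5)
        assert hits >= 48  # >= 95% of runs


class TestSeparationCost:
    def test_all_half_memberships_cost_one_for_every_alpha(self):
        grades = _graded()
        p = pd.Series(0.5, index=grades.index)
        for alpha in (1, 5, 10, 100):
            assert separation_cost(p, grades, alpha) == pytest.approx(1.0)

    def test_perfect_separation_direct_substitution(self):
        grades = pd.Series([1, 1, 3, 3], index=list("abcd"))
        p = pd.Series([0.0, 0.0, 1.0, 1.0], index=list("abcd"))
        c = separation_cost(p, grades, alpha=1.0)
        assert c == pytest.approx(2.0 / (1.0 + np.exp(0.5)))
        assert c == pytest.approx(0.7551, abs=1e-4)
        assert separation_cost(p, grades, alpha=100.0) < 1e-20

    def test_worst_case_approaches_two(self):
        grades = pd.Series([1, 1, 3, 3], index=list("abcd"))
        p = pd.Series([1.0, 1.0, 0.0, 0.0], index=list("abcd"))
        assert separation_cost(p, grades, alpha=1.0) == pytest.approx(1.2449, abs=1e-4)
        assert separation_cost(p, grades, alpha=100.0) == pytest.approx(2.0, abs=1e-10)

    def test_bounds_and_grade2_exclusion(self):
        rng = np.random.default_rng(0)
        grades = _graded()
        p = pd.Series(rng.uniform(size=len(grades)), index=grades.index)
        c = separation_cost(p, grades, alpha=5.0)
        assert 0 < c < 2
        # changing grade-2 memberships never moves the cost
        p2 = p.copy()
        p2[grades == 2] = rng.uniform(size=(grades == 2).sum())
        assert separation_cost(p2, grades, alpha=5.0) == pytest.approx(c)

    def test_cost_decreases_with_alpha_when_separated(self):
        grades = pd.Series([1, 1, 3, 3], index=list("abcd"))
        p = pd.Series([0.2, 0.3, 0.7, 0.8], index=list("abcd"))
        costs = [separation_cost(p, grades, a) for a in (1, 5, 10, 100)]
        assert all(np.diff(costs) < 0)

    def test_empty_grade_is_an_error(self):
        grades = pd.Series([1, 1], index=list("ab"))
        p = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(ValueError, match="grade 3"):
            separation_cost(p, grades, alpha=1.0)


def _signal_pool(seed=0, n_noise=5):
    """One grade-separating feature plus pure-noise features."""
    rng = np.random.default_rng(seed)
    n1, n2, n3 = 15, 8, 12
    grades = _graded(n1, n2, n3)
    signal = np.concatenate(
        [rng.normal(-2, 0.5, n1), rng.normal(0, 0.5, n2), rng.normal(2, 0.5, n3)]
    )
    cols = {"signal": signal}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(size=len(grades))
    frame = pd.DataFrame(cols, index=grades.index)
    frame = (frame - frame.mean()) / frame.std(ddof=0)
    return FeatureSet(feature_ids=tuple(frame.columns), matrix=frame), grades


class TestFeatureSelection:
    def test_forward_picks_the_separating_feature_first(self):
        hits = 0
        for seed in range(20):
            pool, grades = _signal_pool(seed)
            selected, _ = forward_select(pool, grades, alpha=10.0, seed=seed)
            hits += int(selected[0] == "signal")
        assert hits >= 18

    def test_backward_drops_the_noise_feature(self):
        hits = 0
        for seed in range(20):
            pool, grades = _signal_pool(seed, n_noise=1)
            selected, _ = backward_eliminate(pool, grades, alpha=10.0, seed=seed)
            hits += int("signal" in selected and "noise0" not in selected)
        assert hits >= 18

    def test_duplicate_features_select_only_one(self):
        pool, grades = _signal_pool(0, n_noise=0)
        dup = FeatureSet(
            feature_ids=("signal", "copy"),
            matrix=pool.matrix[["signal", "signal"]].set_axis(
                ["signal", "copy"], axis=1
            ),
        )
        selected, _ = forward_select(dup, grades, alpha=10.0, seed=0)
        assert len(selected) == 1

    def test_single_feature_pool_survives_backward(self):
        pool, grades = _signal_pool(0, n_noise=0)
        selected, cost = backward_eliminate(pool, grades, alpha=10.0, seed=0)
        assert selected == ("signal",)

    def test_greedy_cost_not_worse_than_best_single_feature(self):
        pool, grades = _signal_pool(1)
        _, c_forward = forward_select(pool, grades, alpha=10.0, seed=1)
        from meningrade.reclassify import _evaluate

        singles = [
            _evaluate(pool, (f,), grades, 10.0, {}, 1)[0] for f in pool.feature_ids
        ]
        assert c_forward <= min(singles) + 1e-12

    def test_select_signature_is_deterministic(self):
        pool, grades = _signal_pool(2)
        a = select_signature(pool, grades, seed=3)
        b = select_signature(pool, grades, seed=3)
        pd.testing.assert_frame_equal(a.cost_curves, b.cost_curves)
        assert a.best_features == b.best_features

    def test_permuting_grade2_rows_leaves_signature_unchanged(self):
        pool, grades = _signal_pool(4)
        base = select_signature(pool, grades, seed=5)
        g2 = grades.index[grades == 2]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(g2))
        mat = pool.matrix.copy()
        mat.loc[g2] = mat.loc[g2].to_numpy()[perm]
        shuffled = FeatureSet(feature_ids=pool.feature_ids, matrix=mat)
        again = select_signature(shuffled, grades, seed=5)
        assert again.best_features == base.best_features


class TestReclassifyGrade2:
    def _result_with_p(self, p_values, grades):
        from meningrade.reclassify import MembershipResult

        U = np.column_stack([1 - np.asarray(p_values), np.asarray(p_values)])
        res = MembershipResult(
            membership=pd.DataFrame(U, index=grades.index, columns=[0, 1]),
            centroids=np.zeros((2, 1)),
            fuzzifier=2.0,
            objective=0.0,
            n_iter=1,
            converged=True,
            grade3_cluster=1,
        )
        return res

    def test_threshold_arithmetic(self):
        grades = pd.Series([2, 2, 2], index=list("abc"))
        res = self._result_with_p([0.95, 0.10, 0.5], grades)
        report = reclassify_grade2(res, grades)
        assert list(report.labels) == ["grade3_like", "grade1_like", "intermediate"]
        assert report.counts == {
            "grade1_like": 1,
            "intermediate": 1,
            "grade3_like": 1,
        }

    def test_half_threshold_leaves_only_exact_ties_intermediate(self):
        grades = pd.Series([2, 2, 2], index=list("abc"))
        res = self._result_with_p([0.51, 0.49, 0.5], grades)
        report = reclassify_grade2(res, grades, threshold=0.5)
        assert list(report.labels) == ["grade3_like", "grade1_like", "intermediate"]

    def test_no_grade2_warns_and_returns_empty(self):
        grades = pd.Series([1, 3], index=list("ab"))
        res = self._result_with_p([0.1, 0.9], grades)
        with pytest.warns(UserWarning, match="no grade 2"):
            report = reclassify_grade2(res, grades)
        assert len(report.labels) == 0

    def test_boundary_values_inclusive(self):
        grades = pd.Series([2, 2], index=list("ab"))
        res = self._result_with_p([0.80, 0.20], grades)
        report = reclassify_grade2(res, grades)
        assert list(report.labels) == ["grade3_like", "grade1_like"]
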