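"""Lasso-family solvers against closed forms, SVM, comparison harness."""

import numpy as np
import pytest

from mmlassonet import (
    InputError,
    fit_elastic_net,
    fit_group_lasso,
    fit_lasso,
    fit_sparse_group_lasso,
    roi_groups,
    run_comparison,
    select_features,
    svm_classify,
)


def lasso_objective(X, y, w, lam):
    r = y - X @ w
    return (r @ r) / len(y) + lam * np.abs(w).sum()


def group_objective(X, y, w, groups, lam):
    r = y - X @ w
    pen = sum(np.sqrt(len(g)) * np.linalg.norm(w[g]) for g in groups)
    return r @ r + lam * pen


def sgl_objective(X, y, w, groups, lam1, lam2):
    r = y - X @ w
    return r @ r + lam1 * sum(np.linalg.norm(w[g]) for g in groups) + lam2 * np.abs(w).sum()


def enet_objective(X, y, w, lam1, lam2):
    r = y - X @ w
    return r @ r + lam2 * (w @ w) + lam1 * np.abs(w).sum()


@pytest.fixture
def tall_problem(rng):
    X = rng.standard_normal((50, 8))
    w_true = np.array([2.0, -1.0, 0, 0, 0, 0, 0, 0])
    y = X @ w_true + 0.1 * rng.standard_normal(50)
    return X, y


class TestLasso:
    def test_zero_penalty_is_ols(self, tall_problem):
        X, y = tall_problem
        w = fit_lasso(X, y, 0.0).weights
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(w, ols, atol=1e-8)

    def test_full_shrinkage_above_lambda_max(self, tall_problem):
        X, y = tall_problem
        y = y - y.mean()
        lam_max = 2.0 / len(y) * np.abs(X.T @ y).max()
        w = fit_lasso(X, y, lam_max * 1.001).weights
        np.testing.assert_allclose(w, 0.0, atol=1e-10)

    def test_orthonormal_design_soft_threshold(self, rng):
        # orthonormal columns (X^T X = I): the (1/n)-scaled lasso solution
        # is the soft-threshold of the OLS coefficients at n*lam/2
        X, _ = np.linalg.qr(rng.standard_normal((30, 5)))
        y = rng.standard_normal(30)
        lam = 0.02
        w = fit_lasso(X, y, lam).weights
        ols = X.T @ y
        n = len(y)
        expected = np.sign(ols) * np.maximum(np.abs(ols) - n * lam / 2.0, 0.0)
        np.testing.assert_allclose(w, expected, atol=1e-6)

    def test_negative_lambda_rejected(self, tall_problem):
        X, y = tall_problem
        with pytest.raises(InputError):
            fit_lasso(X, y, -0.1)

    def test_solution_path_continuity(self, tall_problem):
        X, y = tall_problem
        w0 = fit_lasso(X, y, 0.2).weights
        deltas = []
        for dlt in (1e-2, 1e-3, 1e-4):
            w1 = fit_lasso(X, y, 0.2 + dlt).weights
            deltas.append(np.linalg.norm(w1 - w0))
        assert deltas[0] > deltas[1] > deltas[2]
        assert deltas[2] < 1e-3


class TestGroupLasso:
    def test_zero_penalty_is_least_squares(self, tall_problem):
        X, y = tall_problem
        groups = [np.arange(0, 4), np.arange(4, 8)]
        w = fit_group_lasso(X, y, groups, 0.0).weights
        np.testing.assert_allclose(w, np.linalg.lstsq(X, y, rcond=None)[0], atol=1e-8)

    def test_huge_penalty_kills_all_groups(self, tall_problem):
        X, y = tall_problem
        groups = [np.arange(0, 4), np.arange(4, 8)]
        w = fit_group_lasso(X, y, groups, 1e6).weights
        np.testing.assert_allclose(w, 0.0, atol=1e-10)

    def test_groups_jointly_zero_or_active(self, tall_problem):
        X, y = tall_problem
        groups = [np.arange(0, 2), np.arange(2, 8)]
        w = fit_group_lasso(X, y, groups, 30.0).weights
        for g in groups:
            nz = np.abs(w[g]) > 1e-10
            assert nz.all() or (~nz).any()  # no half-dead group
        assert (np.abs(w) > 1e-10).any() and (np.abs(w) < 1e-10).any()

    def test_single_size_one_groups_reduce_to_lasso(self, rng):
        # Eq scale map: group objective has no 1/n factor, so group-lasso
        # at lam equals the (1/n)-scaled lasso at lam/n
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        lam = 2.0
        groups = [np.array([j]) for j in range(3)]
        wg = fit_group_lasso(X, y, groups, lam).weights
        wl = fit_lasso(X, y, lam / len(y)).weights
        np.testing.assert_allclose(wg, wl, atol=1e-6)

    def test_invalid_partition_rejected(self, tall_problem):
        X, y = tall_problem
        with pytest.raises(InputError):
            fit_group_lasso(X, y, [np.array([0, 1])], 0.5)  # incomplete cover


class TestSparseGroupLasso:
    def test_pure_l1_limit_equals_lasso(self, rng):
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        groups = [np.arange(0, 3), np.arange(3, 6)]
        lam2 = 1.5
        w_sgl = fit_sparse_group_lasso(X, y, groups, 0.0, lam2).weights
        w_lasso = fit_lasso(X, y, lam2 / len(y)).weights  # same scale map
        np.testing.assert_allclose(w_sgl, w_lasso, atol=1e-6)

    def test_pure_group_limit_is_unweighted_group_lasso(self, rng):
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        groups = [np.arange(0, 3), np.arange(3, 6)]
        lam1 = 4.0
        w = fit_sparse_group_lasso(X, y, groups, lam1, 0.0).weights
        # optimality spot-check under the unweighted-group objective
        obj = sgl_objective(X, y, w, groups, lam1, 0.0)
        for other in (np.zeros(6), np.linalg.lstsq(X, y, rcond=None)[0]):
            assert obj <= sgl_objective(X, y, other, groups, lam1, 0.0) + 1e-8

    def test_objective_beats_degenerate_solutions(self, rng):
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        groups = [np.arange(0, 3), np.arange(3, 6)]
        lam1, lam2 = 2.0, 1.0
        w = fit_sparse_group_lasso(X, y, groups, lam1, lam2).weights
        obj = sgl_objective(X, y, w, groups, lam1, lam2)
        w_l1 = fit_sparse_group_lasso(X, y, groups, 0.0, lam2).weights
        w_gl = fit_sparse_group_lasso(X, y, groups, lam1, 0.0).weights
        assert obj <= sgl_objective(X, y, w_l1, groups, lam1, lam2) + 1e-8
        assert obj <= sgl_objective(X, y, w_gl, groups, lam1, lam2) + 1e-8


class TestElasticNet:
    def test_zero_l2_is_lasso(self, rng):
        X = rng.standard_normal((25, 5))
        y = rng.standard_normal(25)
        lam1 = 1.0
        w_en = fit_elastic_net(X, y, lam1, 0.0).weights
        w_l = fit_lasso(X, y, lam1 / len(y)).weights  # scale map: no 1/n in enet Eq
        np.testing.assert_allclose(w_en, w_l, atol=1e-6)

    def test_zero_l1_matches_ridge_closed_form(self, rng):
        X = rng.standard_normal((25, 5))
        y = rng.standard_normal(25)
        lam2 = 2.5
        w = fit_elastic_net(X, y, 0.0, lam2).weights
        ridge = np.linalg.solve(X.T @ X + lam2 * np.eye(5), X.T @ y)
        np.testing.assert_allclose(w, ridge, atol=1e-6)

    def test_both_zero_is_ols(self, tall_problem):
        X, y = tall_problem
        w = fit_elastic_net(X, y, 0.0, 0.0).weights
        np.testing.assert_allclose(w, np.linalg.lstsq(X, y, rcond=None)[0], atol=1e-8)


class TestSolverOptimality:
    """Every solver's returned objective beats the trivial reference points."""

    def test_objectives_beat_zero_and_ols(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        groups = [np.arange(0, 3), np.arange(3, 6)]
        zero = np.zeros(6)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]

        w = fit_lasso(X, y, 0.4).weights
        for ref in (zero, ols):
            assert lasso_objective(X, y, w, 0.4) <= lasso_objective(X, y, ref, 0.4) + 1e-8

        w = fit_group_lasso(X, y, groups, 3.0).weights
        for ref in (zero, ols):
            assert group_objective(X, y, w, groups, 3.0) <= group_objective(X, y, ref, groups, 3.0) + 1e-8

        w = fit_sparse_group_lasso(X, y, groups, 2.0, 1.0).weights
        for ref in (zero, ols):
            assert sgl_objective(X, y, w, groups, 2.0, 1.0) <= sgl_objective(X, y, ref, groups, 2.0, 1.0) + 1e-8

        w = fit_elastic_net(X, y, 1.0, 1.0).weights
        for ref in (zero, ols):
            assert enet_objective(X, y, w, 1.0, 1.0) <= enet_objective(X, y, ref, 1.0, 1.0) + 1e-8


class TestSelectFeatures:
    def test_zero_weights_empty(self):
        from mmlassonet.baselines import LinearSelector

        sel = LinearSelector(weights=np.zeros(4), method="lasso", hyperparams={})
        assert select_features(sel).size == 0

    def test_tolerance_rule(self):
        from mmlassonet.baselines import LinearSelector

        sel = LinearSelector(
            weights=np.array([0.0, 3.0, -2e-12]), method="lasso", hyperparams={}
        )
        np.testing.assert_array_equal(select_features(sel), [1])


class TestSvmClassify:
    def test_separable_toy_data_perfect_training(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        pred, _ = svm_classify(X, y, X)
        assert (pred == y).all()

    def test_duplicated_eval_row_identical_prediction(self, rng):
        X = rng.standard_normal((20, 3))
        y = (X[:, 0] > 0).astype(int)
        Xe = np.vstack([X[0], X[0]])
        pred, scores = svm_classify(X, y, Xe)
        assert pred[0] == pred[1]
        assert scores[0] == scores[1]

    def test_hand_derived_hyperplane_on_and_data(self):
        # AND-structured corners: only (1,1) positive; the max-margin linear
        # separator is x1 + x2 = 1.5 -> check label consistency
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 0, 0, 1])
        grid = np.array([[0.9, 0.9], [0.2, 0.9], [1.2, 1.1]])
        pred, _ = svm_classify(X, y, grid, C=1e6)  # hard-margin limit
        expected = (grid.sum(axis=1) >= 1.5).astype(int)
        np.testing.assert_array_equal(pred, expected)

    def test_empty_feature_fallback_majority(self, rng):
        y = np.array([0, 0, 0, 1])
        with pytest.warns(UserWarning):
            pred, _ = svm_classify(np.empty((4, 0)), y, np.empty((3, 0)))
        np.testing.assert_array_equal(pred, 0)


class TestRunComparison:
    def test_report_shape_and_deterministic_sd(self, small_cohort):
        rep = run_comparison(small_cohort, ["lasso", "enet"], repeats=3, seed=0)
        table = rep.to_table()
        assert table.shape == (2, 5)
        # deterministic pipelines: zero spread across repeats
        assert rep.sd["lasso"].acc == 0.0
        assert rep.sd["enet"].acc == 0.0

    def test_bit_reproducible(self, small_cohort):
        from mmlassonet import PathConfig

        cfg = PathConfig(epochs_per_lambda=10, hidden_K=8)
        r1 = run_comparison(small_cohort, ["mmlassonet"], repeats=2, seed=3, path_config=cfg)
        r2 = run_comparison(small_cohort, ["mmlassonet"], repeats=2, seed=3, path_config=cfg)
        assert r1.mean["mmlassonet"].acc == r2.mean["mmlassonet"].acc
        assert r1.sd["mmlassonet"].acc == r2.sd["mmlassonet"].acc

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(InputError):
            run_comparison(small_cohort, ["nope"], repeats=1, seed=0)

    def test_multimodal_at_least_matches_lasso_on_signal_cohort(self):
        """On the default signal-bearing cohort the multi-modal network's
        mean test accuracy is within 0.05 of (or above) lasso+SVM."""
        from mmlassonet import CohortConfig, generate_cohort

        mm_acc, lasso_acc = [], []
        for seed in range(5):
            ds = generate_cohort(CohortConfig(seed=seed))
            rep = run_comparison(ds, ["lasso", "mmlassonet"], repeats=1, seed=seed)
            lasso_acc.append(rep.mean["lasso"].acc)
            mm_acc.append(rep.mean["mmlassonet"].acc)
        assert np.mean(mm_acc) >= np.mean(lasso_acc) - 0.05

    def test_roi_groups_partition(self):
        groups = roi_groups(T=5, R=4)
        assert len(groups) == 4
        np.testing.assert_array_equal(np.concatenate(groups), np.arange(20))
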