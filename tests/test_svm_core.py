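"""Solver correctness against independent oracles plus kernel/bandwidth units.

The dual of the bias-free binary reduction is a box-constrained concave QP,
so an L-BFGS-B maximization of it is a fully independent reference for the
coordinate-decomposition solver; scikit-learn's SVC (which fits an
intercept the reduction does not have) serves only as a loose prediction
cross-check on well-separated data.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from gisthsi.svm_core import (SVMModel, TrainingSet, decision_values, load_model,
                              median_sigma2, predict, primal_objective, rbf,
                              rbf_kernel, save_model, train)


def toy_set(X, y, specimen="s"):
    X = np.asarray(X, float)
    pixels = np.column_stack([np.zeros(len(X), int), np.arange(len(X))])
    return TrainingSet(X=X, y=np.asarray(y), pixels=pixels,
                       specimen_ids=np.array([specimen] * len(X)))


def separable_set(n=20, seed=0, gap=4.0):
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0.0, 0.5, size=(n // 2, 3))
    Xb = rng.normal(gap, 0.5, size=(n // 2, 3))
    X = np.vstack([Xa, Xb])
    y = np.array(["gist"] * (n // 2) + ["normal"] * (n // 2))
    return toy_set(X, y)


def oracle_dual(K, s, C_eff):
    """Independent QP reference: maximize the dual with L-BFGS-B."""
    Q = (s[:, None] * s[None, :]) * K
    m = len(s)

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a), -(1.0 - Q @ a)

    res = minimize(neg_dual, np.full(m, min(C_eff, 1.0) / 2), jac=True,
                   method="L-BFGS-B", bounds=[(0.0, C_eff)] * m,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return res.x


def oracle_objective(X, s, alpha, K, C_eff):
    """Multiclass-hinge objective evaluated at a dual point of the reduction."""
    u = K @ (alpha * s)
    xi = np.maximum(0.0, 1.0 - s * u)
    w2 = alpha @ (s * u)
    return 0.25 * w2 + (C_eff / 2.0) * xi.sum()


class TestMedianSigma2:
    def test_single_pair(self):
        assert median_sigma2(np.array([[0.0, 0.0], [3.0, 4.0]])) == 25.0

    def test_odd_count_median(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert median_sigma2(X) == 1.0

    def test_even_count_takes_mean_of_central(self):
        X = np.array([[0.0], [1.0], [3.0], [7.0]])
        # pairwise squared distances: 1, 9, 49, 4, 36, 16 -> median (9+16)/2
        assert median_sigma2(X) == 12.5

    def test_scaling_homogeneity(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        assert median_sigma2(3.0 * X) == pytest.approx(9.0 * median_sigma2(X))

    def test_permutation_and_translation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 4))
        ref = median_sigma2(X)
        assert median_sigma2(X[rng.permutation(7)]) == pytest.approx(ref)
        assert median_sigma2(X + 5.0) == pytest.approx(ref)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            median_sigma2(np.ones((4, 2)))


class TestRBF:
    def test_identical_points_give_one(self):
        x = np.array([1.0, 2.0])
        assert rbf(x, x, 2.0) == 1.0

    def test_distance_equal_bandwidth_gives_inv_e(self):
        assert rbf(np.zeros(2), np.array([1.0, 1.0]), 2.0) == pytest.approx(
            np.exp(-1.0))

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rbf(np.zeros(2), np.ones(2), 0.0)

    def test_kernel_matrix_symmetric_psd(self):
        X = np.random.default_rng(2).normal(size=(10, 4))
        K = rbf_kernel(X, X, median_sigma2(X))
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        eigs = np.linalg.eigvalsh(K)
        assert eigs.min() > -1e-10


class TestTrainAgainstOracles:
    def test_two_point_problem_matches_grid_search(self):
        # one dual variable per point; symmetry makes them equal, so the
        # optimum is found by brute force over a single free variable
        ts = toy_set([[0.0, 0.0], [2.0, 0.0]], ["gist", "normal"])
        model = train(ts, C=1.0, sigma2=2.0)
        K12 = rbf(np.array([0.0, 0.0]), np.array([2.0, 0.0]), 2.0)
        grid = np.linspace(0.0, model.C_eff, 20001)
        dual = 2 * grid - (grid ** 2) * (1.0 - K12)   # W(a, a)
        a_star = grid[np.argmax(dual)]
        np.testing.assert_allclose(np.abs(model.dual_coef),
                                   [a_star, a_star], rtol=1e-2)
        # midpoint decision value is zero by symmetry
        mid = decision_values(model, np.array([[1.0, 0.0]]))
        assert mid[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert predict(model, ts.X).tolist() == ["gist", "normal"]

    @pytest.mark.parametrize("c_mode", ["per-sample", "absolute"])
    def test_objective_matches_qp_oracle_on_random_sets(self, c_mode):
        rng = np.random.default_rng(7)
        for trial in range(10):
            m = int(rng.integers(4, 13))
            X = rng.normal(size=(m, 3))
            y = np.array(["gist", "normal"])[rng.integers(0, 2, m)]
            if len(set(y)) < 2:
                y[0], y[1] = "gist", "normal"
            ts = toy_set(X, y)
            model = train(ts, C=1.0, c_mode=c_mode, tol=1e-6)
            ts_c = ts.canonical_order()
            s = np.where(ts_c.y == "gist", 1.0, -1.0)
            K = rbf_kernel(ts_c.X, ts_c.X, model.sigma2)
            a_ref = oracle_dual(K, s, model.C_eff)
            obj_ref = oracle_objective(ts_c.X, s, a_ref, K, model.C_eff)
            obj = primal_objective(model)
            assert obj == pytest.approx(obj_ref, rel=1e-6, abs=1e-9)

    def test_duplicating_training_points_keeps_decision(self):
        ts = separable_set(n=10, seed=3)
        doubled = TrainingSet(
            X=np.vstack([ts.X, ts.X]), y=np.concatenate([ts.y, ts.y]),
            specimen_ids=np.concatenate([ts.specimen_ids,
                                         np.array(["t"] * len(ts))]),
            pixels=None)
        probe = np.random.default_rng(4).normal(1.5, 1.0, size=(20, 3))
        # absolute C: duplication halves per-copy alphas, decision unchanged
        f1 = decision_values(train(ts, c_mode="absolute", sigma2=2.0,
                                   tol=1e-6), probe)
        f2 = decision_values(train(doubled, c_mode="absolute", sigma2=2.0,
                                   tol=1e-6), probe)
        np.testing.assert_allclose(f1, f2, atol=5e-4)

    def test_separable_set_fits_with_zero_errors(self):
        ts = separable_set()
        model = train(ts, c_mode="absolute", C=10.0)
        assert predict(model, ts.X).tolist() == ts.y.tolist()
        assert model.xi.max() <= 1e-2

    def test_sklearn_prediction_cross_check(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        ts = separable_set(n=30, seed=9)
        model = train(ts, c_mode="absolute", C=1.0)
        clf = sklearn_svm.SVC(C=1.0, kernel="rbf", gamma=1.0 / model.sigma2)
        clf.fit(ts.X, ts.y)
        probe = np.random.default_rng(5).normal(2.0, 2.0, size=(50, 3))
        agree = np.mean(predict(model, probe) == clf.predict(probe))
        assert agree >= 0.95

    def test_slack_vanishes_as_C_grows_on_separable_data(self):
        ts = separable_set(n=16, seed=1)
        slacks = [train(ts, C=C, c_mode="absolute").xi.sum()
                  for C in (0.1, 10.0, 1000.0)]
        assert slacks[-1] <= slacks[0] + 1e-9
        assert slacks[-1] < 1e-2

    def test_single_class_rejected(self):
        ts = toy_set([[0.0], [1.0]], ["gist", "gist"])
        with pytest.raises(ValueError, match="2 classes"):
            train(ts)

    def test_nonconvergence_reports_diagnostics(self):
        ts = separable_set(n=12, seed=2)
        with pytest.raises(RuntimeError, match="did not converge"):
            train(ts, max_updates=1)


class TestPredictProperties:
    def test_scores_at_support_vectors_reproduce_training(self):
        ts = separable_set(n=12, seed=6)
        model = train(ts, c_mode="absolute")
        ts_c = ts.canonical_order()
        s = np.where(ts_c.y == "gist", 1.0, -1.0)
        f = decision_values(model, ts_c.X)[:, 0] * 2.0
        xi = np.maximum(0.0, 1.0 - s * f)
        np.testing.assert_allclose(xi, model.xi, atol=1e-8)

    def test_score_difference_antisymmetric(self):
        ts = separable_set(n=10, seed=8)
        model = train(ts)
        scores = decision_values(model, ts.X)
        np.testing.assert_allclose(scores[:, 0], -scores[:, 1], atol=1e-12)

    def test_class_swap_flips_decision_sign(self):
        ts = separable_set(n=10, seed=8)
        swapped = TrainingSet(ts.X, np.where(ts.y == "gist", "normal", "gist"),
                              ts.specimen_ids, ts.pixels)
        f = decision_values(train(ts, sigma2=3.0, tol=1e-6), ts.X)[:, 0]
        g = decision_values(train(swapped, sigma2=3.0, tol=1e-6), ts.X)[:, 0]
        np.testing.assert_allclose(f, -g, atol=1e-4)

    def test_tie_takes_first_class_code(self):
        model = SVMModel(support_vectors=np.zeros((1, 2)),
                         dual_coef=np.zeros(1), sigma2=1.0, C=1.0, C_eff=1.0,
                         classes=("gist", "normal"), n_train=2,
                         xi=np.zeros(2), w2=0.0, n_updates=0)
        assert predict(model, np.array([[5.0, 5.0]])).tolist() == ["gist"]

    def test_row_permutation_equivariance(self):
        ts = separable_set(n=14, seed=10)
        model = train(ts)
        probe = np.random.default_rng(3).normal(2, 2, size=(9, 3))
        perm = np.random.default_rng(4).permutation(9)
        np.testing.assert_array_equal(predict(model, probe)[perm],
                                      predict(model, probe[perm]))

    def test_scores_lipschitz_in_input(self):
        ts = separable_set(n=14, seed=12)
        model = train(ts, c_mode="absolute")
        # |f(x) - f(x')| <= (sum |coef|) * sqrt(2/(e*sigma2)) * ||x - x'||
        lip = np.abs(model.dual_coef).sum() * np.sqrt(
            2.0 / (np.e * model.sigma2))
        rng = np.random.default_rng(13)
        x = rng.normal(2, 1, size=(1, 3))
        for eps in (1e-3, 1e-2):
            dx = rng.normal(size=(1, 3))
            dx *= eps / np.linalg.norm(dx)
            df = decision_values(model, x + dx) - decision_values(model, x)
            assert abs(df[0, 0]) * 2 <= lip * eps + 1e-12

    def test_feature_dimension_mismatch_rejected(self):
        model = train(separable_set())
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((2, 7)))

    def test_dual_coefficients_within_box(self):
        for c_mode in ("per-sample", "absolute"):
            model = train(separable_set(n=12, seed=5), c_mode=c_mode)
            a = np.abs(model.dual_coef)
            assert np.all(a > 0) and np.all(a <= model.C_eff + 1e-12)


class TestModelSerialization:
    def test_round_trip_reproduces_decisions(self, tmp_path):
        ts = separable_set()
        model = train(ts)
        path = save_model(model, tmp_path / "m.npz")
        back = load_model(path)
        np.testing.assert_array_equal(decision_values(back, ts.X),
                                      decision_values(model, ts.X))
        assert back.classes == model.classes


class TestTrainingSetContainer:
    def test_duplicate_specimen_pixel_rejected(self):
        X = np.zeros((2, 3))
        pix = np.array([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="duplicate"):
            TrainingSet(X, np.array(["gist", "normal"]),
                        np.array(["s", "s"]), pix)

    def test_canonical_order_is_concat_invariant(self):
        a = separable_set(n=8, seed=0)
        b = toy_set(np.random.default_rng(1).normal(size=(4, 3)),
                    ["gist", "normal", "gist", "normal"], specimen="b")
        one = TrainingSet.concat([a, b]).canonical_order()
        other = TrainingSet.concat([b, a]).canonical_order()
        np.testing.assert_array_equal(one.X, other.X)
        np.testing.assert_array_equal(one.y, other.y)

    def test_stratified_subsample_caps_classes(self):
        ts = separable_set(n=20)
        sub = ts.stratified_subsample(4, seed=0)
        assert int(np.sum(sub.y == "gist")) == 4
        assert int(np.sum(sub.y == "normal")) == 4
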