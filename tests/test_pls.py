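"""PLS machinery against independent oracles: least squares, SVD, naive
leave-one-out loops, brute-force sign enumeration, and scikit-learn."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dfle import (
    PressCurve,
    fit_pls,
    loading_correlations,
    loo_press,
    predict,
    predict_components,
    select_components,
    simulate_latent_pls,
    standardize,
    two_stage_fit,
    van_der_voet,
    vip,
)


def _toy(rng, n=12, p=4, q=2):
    X = rng.standard_normal((n, p))
    Y = X @ rng.standard_normal((p, q)) + 0.3 * rng.standard_normal((n, q))
    Zx, _ = standardize(X)
    Zy, _ = standardize(Y)
    return Zx, Zy


class TestStandardize:
    def test_symmetric_three_point_column(self):
        Z, s = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(s.inverse(Z), [[1], [2], [3]])

    def test_output_columns_centred_unit_sd(self, rng):
        Z, _ = standardize(rng.normal(5, 3, size=(30, 4)))
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestFitPls:
    def test_single_predictor_single_response_equals_simple_regression(self, rng):
        x = rng.standard_normal((20, 1))
        y = 2 * x + 0.1 * rng.standard_normal((20, 1))
        Zx, _ = standardize(x)
        Zy, _ = standardize(y)
        fit = fit_pls(Zx, Zy, 1)
        beta = float(Zx[:, 0] @ Zy[:, 0] / (Zx[:, 0] @ Zx[:, 0]))
        np.testing.assert_allclose(predict(fit, Zx), beta * Zx, rtol=1e-10)

    def test_full_rank_fit_equals_least_squares(self, rng):
        Zx, Zy = _toy(rng)
        fit = fit_pls(Zx, Zy, 4)
        # oracle: normal equations solved directly
        beta = np.linalg.solve(Zx.T @ Zx, Zx.T @ Zy)
        np.testing.assert_allclose(predict(fit, Zx), Zx @ beta, atol=1e-8)

    def test_first_weight_is_dominant_left_singular_vector(self, rng):
        Zx, Zy = _toy(rng, n=25, p=6, q=3)
        fit = fit_pls(Zx, Zy, 2)
        U, _, _ = np.linalg.svd(Zx.T @ Zy)
        w_oracle = U[:, 0]
        if w_oracle[np.argmax(np.abs(w_oracle))] < 0:
            w_oracle = -w_oracle
        np.testing.assert_allclose(fit.W[:, 0], w_oracle, atol=1e-8)

    def test_scores_orthogonal_weights_unit_norm(self, rng):
        for _ in range(5):
            Zx, Zy = _toy(rng, n=20, p=5, q=3)
            fit = fit_pls(Zx, Zy, 4)
            gram = fit.T.T @ fit.T
            off = gram - np.diag(np.diag(gram))
            assert np.abs(off).max() < 1e-8
            np.testing.assert_allclose(np.linalg.norm(fit.W, axis=0), 1, rtol=1e-10)
            assert fit.frac_x.sum() <= 1 + 1e-10
            assert fit.frac_y.sum() <= 1 + 1e-10

    def test_matches_scikit_learn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        Zx, Zy = _toy(rng, n=30, p=6, q=2)
        fit = fit_pls(Zx, Zy, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False,
                                    tol=1e-12, max_iter=10_000).fit(Zx, Zy)
        np.testing.assert_allclose(predict(fit, Zx), ref.predict(Zx), atol=1e-6)

    def test_component_count_above_rank_errors(self, rng):
        X = rng.standard_normal((10, 3))
        X = np.hstack([X, X[:, :1]])  # rank 3, p = 4
        Y = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X - X.mean(0), Y - Y.mean(0), 4)

    def test_cumulative_component_predictions_match_truncated_fits(self, rng):
        Zx, Zy = _toy(rng, n=18, p=5, q=2)
        full = fit_pls(Zx, Zy, 4)
        preds = predict_components(full, Zx)
        for k in (1, 2, 3):
            sub = fit_pls(Zx, Zy, k)
            np.testing.assert_allclose(preds[:, :, k - 1], predict(sub, Zx), atol=1e-8)


class TestLooPress:
    def test_null_model_press_matches_explicit_mean_loop(self, rng):
        X = rng.standard_normal((8, 3))
        Y = rng.standard_normal((8, 2))
        curve = loo_press(X, Y, 1)
        expected = 0.0
        for i in range(8):
            for j in range(2):
                others = np.delete(Y[:, j], i)
                expected += (Y[i, j] - others.mean()) ** 2
        assert curve.press[0] == pytest.approx(expected, rel=1e-12)

    def test_one_component_press_matches_naive_double_loop(self, rng):
        # oracle: for q = 1 the single NIPALS component has the closed form
        # w ~ X'y, written here as an explicit independent loop
        X = rng.standard_normal((5, 2))
        y = (X @ np.array([1.0, -0.5]) + 0.2 * rng.standard_normal(5)).reshape(-1, 1)
        curve = loo_press(X, y, 1)
        expected = 0.0
        for i in range(5):
            idx = [r for r in range(5) if r != i]
            Xtr, ytr = X[idx], y[idx, 0]
            mx, sx = Xtr.mean(0), Xtr.std(0, ddof=1)
            my, sy = ytr.mean(), ytr.std(ddof=1)
            Zx = (Xtr - mx) / sx
            zy = (ytr - my) / sy
            w = Zx.T @ zy
            w = w / np.sqrt(w @ w)
            t = Zx @ w
            c = (zy @ t) / (t @ t)
            pred = ((X[i] - mx) / sx) @ w * c * sy + my
            expected += (y[i, 0] - pred) ** 2
        assert curve.press[1] == pytest.approx(expected, rel=1e-10)

    def test_press_nonnegative_and_signal_reduces_it(self, rng):
        X, Y, _ = simulate_latent_pls(n=30, p_informative=6, n_factors=2, seed=4)
        curve = loo_press(X, Y, 3)
        assert (curve.press >= 0).all()
        assert curve.press[2] < curve.press[0]
        assert curve.press_by_response.shape == (4, 2)
        np.testing.assert_allclose(curve.press_by_response.sum(axis=1), curve.press)

    def test_requested_components_above_fold_rank_error(self, rng):
        X = rng.standard_normal((6, 2))
        Y = rng.standard_normal((6, 1))
        with pytest.raises(ValueError, match="rank"):
            loo_press(X, Y, 3)


class TestVanDerVoet:
    def test_model_against_itself(self, rng):
        res = rng.standard_normal((12, 2))
        C, p = van_der_voet(res, res)
        assert C == 0.0 and p == 1.0

    def test_three_unit_differences_enumerate_to_quarter(self):
        res_k = np.ones((3, 1))
        res_ref = np.zeros((3, 1))
        C, p = van_der_voet(res_k, res_ref)
        assert C == pytest.approx(3.0)
        assert p == pytest.approx(2 / 8)

    def test_exact_enumeration_matches_brute_force(self, rng):
        for n in (4, 7, 10):
            a = rng.standard_normal((n, 2))
            b = rng.standard_normal((n, 2))
            C, p = van_der_voet(a, b)
            d = (a ** 2 - b ** 2).sum(axis=1)
            hits = sum(abs(np.dot(signs, d)) >= abs(d.sum()) - 1e-12
                       for signs in itertools.product([1, -1], repeat=n))
            assert p == pytest.approx(hits / 2 ** n)

    def test_p_value_in_half_open_unit_interval(self, rng):
        for n in (5, 30):
            a = rng.standard_normal((n, 1))
            b = rng.standard_normal((n, 1))
            _, p = van_der_voet(a, b, n_rand=499, seed=1)
            assert 0 < p <= 1

    def test_row_permutation_invariance_under_exact_enumeration(self, rng):
        a = rng.standard_normal((9, 2))
        b = rng.standard_normal((9, 2))
        perm = rng.permutation(9)
        C1, p1 = van_der_voet(a, b)
        C2, p2 = van_der_voet(a[perm], b[perm])
        assert C1 == pytest.approx(C2)
        assert p1 == pytest.approx(p2)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="shape"):
            van_der_voet(rng.standard_normal((4, 2)), rng.standard_normal((5, 2)))


class TestSelectComponents:
    @staticmethod
    def _curve_from_residuals(res_by_k):
        residuals = np.stack(res_by_k, axis=-1)
        press = np.sum(residuals ** 2, axis=(0, 1))
        return PressCurve(press=press, residuals=residuals)

    def test_every_smaller_model_significant_forces_k_min(self, rng):
        # k = 0, 1 much worse than k = 2 on every observation
        n = 12
        base = 0.05 * rng.standard_normal((n, 1))
        curve = self._curve_from_residuals([base + 3.0, base + 2.0, base])
        sel = select_components(curve, alpha=0.10, seed=0)
        assert sel.k_min == 2 and sel.selected == 2
        assert sel.table["p_value"].iloc[-1] == 1.0

    def test_single_component_curve_forced(self, rng):
        n = 12
        base = 0.05 * rng.standard_normal((n, 1))
        curve = self._curve_from_residuals([base + 3.0, base])
        sel = select_components(curve, alpha=0.10, seed=0)
        assert sel.selected == 1

    def test_exact_press_tie_breaks_toward_fewer_components(self, rng):
        # k = 1 and k = 2 have sign-flipped (hence identical-PRESS) residuals;
        # k = 0 is clearly worse -> k_min must be the smaller of the tied pair
        res = np.abs(rng.standard_normal((10, 1))) + 0.5
        curve = self._curve_from_residuals([2 * res, res, -res])
        sel = select_components(curve, alpha=0.10, seed=0)
        assert curve.press[1] == curve.press[2]
        assert sel.k_min == 1
        assert sel.selected == 1

    def test_sign_balanced_differences_accept_the_null_model(self, rng):
        # the null model's residuals equal the best model's up to sign, so the
        # paired test has nothing to reject and the selection is parsimonious
        res = rng.standard_normal((10, 1))
        flip = res.copy()
        flip[::2] *= -1
        curve = self._curve_from_residuals([flip, 1.0000001 * res, res])
        sel = select_components(curve, alpha=0.10, seed=0)
        assert sel.selected == 0

    def test_three_factor_data_recovers_three_components(self):
        X, Y, _ = simulate_latent_pls(n=200, p_informative=20, seed=77)
        sel = select_components(loo_press(X, Y, 10), alpha=0.10, n_rand=1999, seed=77)
        assert sel.selected == 3


class TestVip:
    def test_mean_square_is_one(self, rng):
        Zx, Zy = _toy(rng, n=20, p=6, q=2)
        scores = vip(fit_pls(Zx, Zy, 3))
        assert np.mean(scores ** 2) == pytest.approx(1.0, abs=1e-10)
        assert (scores >= 0).all()

    def test_single_variable_has_unit_vip(self, rng):
        x = rng.standard_normal((15, 1))
        y = x + 0.1 * rng.standard_normal((15, 1))
        Zx, _ = standardize(x)
        Zy, _ = standardize(y)
        assert vip(fit_pls(Zx, Zy, 1)).iloc[0] == pytest.approx(1.0)

    def test_frozen_two_variable_formula(self):
        # K=1, w = (0.6, 0.8): VIP = (sqrt(2*0.36), sqrt(2*0.64))
        from dfle.pls import PLSFit
        fit = PLSFit(W=np.array([[0.6], [0.8]]), P=np.zeros((2, 1)),
                     C=np.zeros((1, 1)), T=np.zeros((5, 1)), B=np.zeros((2, 1)),
                     frac_x=np.array([0.5]), frac_y=np.array([0.4]),
                     x_names=["a", "b"])
        np.testing.assert_allclose(vip(fit).to_numpy(),
                                   [0.848528137423857, 1.1313708498984762])

    def test_no_explained_variance_errors(self):
        from dfle.pls import PLSFit
        fit = PLSFit(W=np.eye(2), P=np.eye(2), C=np.eye(2), T=np.zeros((4, 2)),
                     B=np.eye(2), frac_x=np.array([0.5, 0.2]),
                     frac_y=np.zeros(2))
        with pytest.raises(ValueError, match="VIP"):
            vip(fit)


class TestLoadingCorrelations:
    def test_variable_equal_to_score_has_unit_correlation(self, rng):
        Zx, Zy = _toy(rng, n=20, p=5, q=2)
        fit = fit_pls(Zx, Zy, 2)
        X_aug = np.hstack([Zx, fit.T[:, :1]])
        tab = loading_correlations(fit, pd.DataFrame(X_aug), pd.DataFrame(Zy))
        self_corr = tab[(tab.variable == 5) & (tab.component == 1)]
        assert self_corr["correlation"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_variable_has_zero_correlation(self, rng):
        Zx, Zy = _toy(rng, n=20, p=4, q=2)
        fit = fit_pls(Zx, Zy, 1)
        t = fit.T[:, 0]
        v = rng.standard_normal(20)
        v -= (v @ t) / (t @ t) * t
        v -= v.mean()
        tab = loading_correlations(fit, pd.DataFrame(np.column_stack([Zx, v])),
                                   pd.DataFrame(Zy))
        ortho = tab[(tab.variable == 4) & (tab.component == 1)]
        assert abs(ortho["correlation"].iloc[0]) < 1e-10

    def test_matches_direct_pearson_formula(self, rng):
        Zx, Zy = _toy(rng, n=6, p=3, q=1)
        fit = fit_pls(Zx, Zy, 2)
        tab = loading_correlations(fit, pd.DataFrame(Zx, columns=list("abc")),
                                   pd.DataFrame(Zy, columns=["y"]))
        for k in (1, 2):
            t = fit.T[:, k - 1]
            for j, name in enumerate("abc"):
                x = Zx[:, j]
                num = np.sum((x - x.mean()) * (t - t.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((t - t.mean()) ** 2))
                got = tab[(tab.variable == name) & (tab.component == k)]
                assert got["correlation"].iloc[0] == pytest.approx(num / den)


class TestTwoStageFit:
    def test_zero_threshold_keeps_stage_two_identical(self):
        X, Y, _ = simulate_latent_pls(n=15, p_informative=4, n_factors=2,
                                      y_noise_sd=0.3, seed=5)
        res = two_stage_fit(X, Y, vip_threshold=0.0, k_max=3, seed=1)
        assert res.retained == list(X.columns)
        assert res.stage1.selected == res.stage2.selected
        np.testing.assert_allclose(res.fit1.B, res.fit2.B, atol=1e-12)

    def test_all_variables_above_threshold_is_noop_pruning(self):
        X, Y, _ = simulate_latent_pls(n=15, p_informative=3, n_factors=2,
                                      y_noise_sd=0.3, seed=6)
        res = two_stage_fit(X, Y, vip_threshold=0.0, k_max=2, seed=2)
        assert (res.vip1 >= 0).all() and res.retained == list(X.columns)
        np.testing.assert_allclose(res.fit1.B, res.fit2.B, atol=1e-12)

    def test_impossible_threshold_errors(self):
        X, Y, _ = simulate_latent_pls(n=15, p_informative=4, n_factors=2,
                                      y_noise_sd=0.3, seed=7)
        with pytest.raises(ValueError, match="VIP"):
            two_stage_fit(X, Y, vip_threshold=100.0, k_max=3, seed=3)

    def test_noise_columns_get_low_vip(self):
        X, Y, _ = simulate_latent_pls(n=100, p_informative=10, p_noise=10, seed=8)
        res = two_stage_fit(X, Y, vip_threshold=0.8, k_max=5, seed=4)
        noise_cols = [c for c in X.columns if c.startswith("noise_")]
        dropped = [c for c in noise_cols if c not in res.retained]
        assert len(dropped) >= 8
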