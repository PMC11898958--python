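"""Splits, validation metrics, applicability domain and acceptability."""

import numpy as np
import pytest

import bioqsrr as b


class TestSplit:
    def test_sizes_12_6(self, table1):
        tr, ext = b.split_train_validation(table1, "chi_c18", n_tr=12)
        assert len(tr) == 12 and len(ext) == 6
        assert sorted(tr + ext) == list(range(18))

    def test_ranked_deterministic(self, table1):
        s1 = b.split_train_validation(table1, "chi_iam")
        s2 = b.split_train_validation(table1, "chi_iam")
        assert s1 == s2

    def test_ranked_keeps_extremes_in_training(self, table1):
        for col in ("chi_c18", "chi_iam", "logk_hsa"):
            tr, ext = b.split_train_validation(table1, col)
            y = table1.column(col)
            assert int(np.argmin(y)) in tr
            assert int(np.argmax(y)) in tr

    def test_random_split_seeded(self):
        y = np.arange(18.0)
        a = b.split_train_validation(y, n_tr=12, method="random", seed=5)
        b2 = b.split_train_validation(y, n_tr=12, method="random", seed=5)
        c = b.split_train_validation(y, n_tr=12, method="random", seed=6)
        assert a == b2 and a != c

    def test_n_tr_too_large(self):
        with pytest.raises(ValueError):
            b.split_train_validation(np.arange(10.0), n_tr=10)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        r2, rmse = b.regression_metrics(y, y)
        assert r2 == 1.0 and rmse == 0.0

    def test_null_model_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, _ = b.regression_metrics(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_sums_oracle(self):
        y_obs = np.array([1.0, 2.0, 3.0, 4.0])
        y_pred = np.array([1.1, 1.9, 3.2, 3.8])
        ss_res = 0.01 + 0.01 + 0.04 + 0.04
        ss_tot = 2.25 + 0.25 + 0.25 + 2.25
        r2, rmse = b.regression_metrics(y_obs, y_pred)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)
        assert rmse == pytest.approx(np.sqrt(ss_res / 4))

    def test_constant_y_obs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            b.regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestLOO:
    def test_exact_linear_data(self):
        X = np.arange(8.0).reshape(-1, 1)
        y = 3.0 * X.ravel() + 1.0
        y_cv, q2, rmse = b.loo_cross_validate(X, y)
        assert q2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(y_cv, y, atol=1e-10)

    def test_matches_bruteforce_refit_oracle(self, rng):
        X = rng.standard_normal((8, 2))
        y = X @ [1.5, -0.7] + rng.normal(0, 0.3, 8)
        y_cv, q2, rmse = b.loo_cross_validate(X, y)
        # oracle: n separate refits, each without row i
        y_cv_oracle = np.empty(8)
        for i in range(8):
            keep = [j for j in range(8) if j != i]
            m = b.fit_mlr(X[keep], y[keep])
            y_cv_oracle[i] = m.predict(X[i : i + 1])[0]
        np.testing.assert_allclose(y_cv, y_cv_oracle, rtol=1e-9, atol=1e-9)
        press = np.sum((y_cv_oracle - y) ** 2)
        assert q2 == pytest.approx(1 - press / np.sum((y - y.mean()) ** 2))
        assert rmse == pytest.approx(np.sqrt(press / 8))

    def test_q2_never_exceeds_r2(self, rng):
        """Q2_LOO <= R2 for OLS, and RMSE_LOO >= RMSE_TR, across 100 datasets."""
        for _ in range(100):
            n = int(rng.integers(8, 16))
            X = rng.standard_normal((n, 2))
            y = X @ rng.normal(size=2) + rng.normal(0, 0.5, n)
            m = b.fit_mlr(X, y)
            r2, rmse_tr = b.regression_metrics(y, m.predict(X))
            _, q2, rmse_loo = b.loo_cross_validate(X, y)
            assert q2 <= r2 + 1e-12
            assert rmse_loo >= rmse_tr - 1e-12

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= p"):
            b.loo_cross_validate(rng.standard_normal((4, 2)), np.arange(4.0))


class TestCCC:
    def test_perfect_concordance(self):
        y = np.array([1.0, 2.0, 5.0])
        assert b.ccc_ext(y, y) == pytest.approx(1.0)

    def test_shift_penalty_monotone_to_zero(self):
        y = np.arange(10.0)
        vals = [b.ccc_ext(y, y + s) for s in (0.0, 1.0, 10.0, 100.0)]
        assert all(a > bb for a, bb in zip(vals, vals[1:]))
        assert vals[-1] < 0.01

    def test_hand_computed_oracle(self):
        yo = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yp = np.array([1.2, 1.8, 3.4, 3.9, 5.1])
        sxy = np.sum((yo - yo.mean()) * (yp - yp.mean()))
        denom = (
            np.sum((yo - yo.mean()) ** 2)
            + np.sum((yp - yp.mean()) ** 2)
            + 5 * (yo.mean() - yp.mean()) ** 2
        )
        assert b.ccc_ext(yo, yp) == pytest.approx(2 * sxy / denom)

    def test_bounded_and_below_pearson(self, rng):
        """|CCC| <= |Pearson r| (Lin's inequality), 100 random pairs."""
        for _ in range(100):
            yo = rng.standard_normal(12)
            yp = rng.standard_normal(12)
            ccc = b.ccc_ext(yo, yp)
            r = np.corrcoef(yo, yp)[0, 1]
            assert -1 - 1e-12 <= ccc <= 1 + 1e-12
            assert abs(ccc) <= abs(r) + 1e-12

    def test_both_constant_rejected(self):
        with pytest.raises(ValueError):
            b.ccc_ext([1.0, 1.0], [2.0, 2.0])


class TestLeverages:
    def test_query_at_mean_is_one_over_n(self, rng):
        x = rng.standard_normal(10).reshape(-1, 1)
        h = b.leverages(x, np.array([[x.mean()]]))
        assert h[0] == pytest.approx(1.0 / 10)

    def test_trace_identity(self, rng):
        """Sum of training self-leverages = p + 1 (hat-matrix trace)."""
        for p in (1, 2, 4):
            X = rng.standard_normal((15, p))
            assert b.leverages(X).sum() == pytest.approx(p + 1, abs=1e-8)

    def test_far_query_exceeds_training_leverage(self, rng):
        X = rng.standard_normal((12, 2))
        far = np.array([[50.0, -50.0]])
        assert b.leverages(X, far)[0] > b.leverages(X).max()

    def test_singular_design_rejected(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="singular"):
            b.leverages(X)


class TestCriticalLeverage:
    def test_closed_form_cases(self):
        assert b.critical_leverage(2, 12) == pytest.approx(6.0 / 11.0)
        assert b.critical_leverage(1, 4) == pytest.approx(1.0)

    def test_linear_in_p(self):
        assert b.critical_leverage(4, 12) == pytest.approx(2 * b.critical_leverage(2, 12))

    def test_degenerate_n(self):
        with pytest.raises(ValueError):
            b.critical_leverage(2, 1)


class TestWilliams:
    @pytest.fixture()
    def simulated(self, rng):
        # compact (uniform) design: leverage tail stays below h*
        X = rng.uniform(-1, 1, (60, 2))
        y = 5.0 + X @ [2.0, -1.0] + rng.normal(0, 0.3, 60)
        model = b.fit_mlr(X, y)
        return X, y, model

    def test_well_specified_mostly_in_domain(self, simulated):
        X, y, model = simulated
        dom = b.williams_assessment(model, X, y)
        assert dom.in_domain.mean() >= 0.95

    def test_query_equal_to_training_row(self, simulated):
        X, y, model = simulated
        dom = b.williams_assessment(model, X, y, X_ext=X[:1], y_ext=y[:1])
        assert dom.leverage[len(y)] == pytest.approx(dom.leverage[0])

    def test_boundary_residual_inclusive(self):
        model = b.QSRRModel("y", 0.0, {"x0": 1.0})
        X = np.linspace(-1, 1, 24).reshape(-1, 1)
        rng = np.random.default_rng(2)
        y = X.ravel() + rng.normal(0, 0.1, 24)
        dom = b.williams_assessment(model, X, y)
        # inclusive comparison at exactly 3 sd
        assert np.all(dom.in_domain == ((dom.leverage <= dom.h_star) & (np.abs(dom.std_residual) <= 3.0)))

    def test_three_sigma_coverage_large_n(self):
        """~99.7% of standardized residuals within +-3 on 10^4 points."""
        rng = np.random.default_rng(77)
        X = rng.standard_normal((10_000, 2))
        y = 1.0 + X @ [1.0, 2.0] + rng.normal(0, 1.0, 10_000)
        model = b.fit_mlr(X, y)
        dom = b.williams_assessment(model, X, y)
        frac = np.mean(np.abs(dom.std_residual) <= 3.0)
        se = np.sqrt(0.9973 * 0.0027 / 10_000)
        assert abs(frac - 0.9973) <= 4 * se


class TestAcceptability:
    def test_published_statistics_pass(self, ref_models):
        stats = ref_models["chi_c18"].fit_meta["stats"]
        flags = b.assess_acceptability(stats)
        assert flags == {"r2_ok": True, "r2_ext_ok": True, "overall": True}

    @pytest.mark.parametrize(
        "r2,r2_ext,overall",
        [(0.59, 0.9, False), (0.61, 0.49, False), (0.870, 0.696, True)],
    )
    def test_threshold_rule(self, r2, r2_ext, overall):
        flags = b.assess_acceptability({"r2_tr": r2, "r2_ext": r2_ext})
        assert flags["overall"] is overall


class TestValidateSplit:
    def test_full_pipeline_consistency(self, rng):
        X = rng.standard_normal((18, 2))
        y = 10.0 + X @ [3.0, -2.0] + rng.normal(0, 0.2, 18)
        tr, ext = b.split_train_validation(y, n_tr=12, method="ranked")
        rep, model = b.validate_split(X[tr], y[tr], X[ext], y[ext])
        assert rep.n_tr == 12 and rep.n_ext == 6
        assert rep.r2_tr > 0.9 and rep.r2_ext > 0.9
        assert rep.ccc_ext == pytest.approx(b.ccc_ext(y[ext], model.predict(X[ext])))
        assert rep.acceptable["overall"]
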