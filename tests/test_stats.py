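"""Statistical conventions: paired tests, FDR, screening, stepwise OLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from motionerp import (
    check_collinearity,
    cohens_d_from_t,
    fdr_adjust,
    paired_ttest,
    pearson_screen,
    r2_adjusted_from_f,
    stepwise_forward,
)
from motionerp.errors import MotionErpError
from motionerp.stats import residual_diagnostics


class TestPairedTest:
    def test_t_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 2, 37)
        b = rng.normal(9, 2, 37)
        res = paired_ttest(a, b)
        diff = a - b
        t_direct = diff.mean() * np.sqrt(37) / diff.std(ddof=1)
        assert res.t == pytest.approx(t_direct, abs=1e-12)
        assert res.df == 36

    @settings(max_examples=30, deadline=None)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_d_equals_t_over_sqrt_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        a = rng.normal(0, 1, n)
        b = rng.normal(0.3, 1, n)
        res = paired_ttest(a, b)
        assert res.d == pytest.approx(res.t / np.sqrt(n), abs=1e-12)

    def test_identical_vectors_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(MotionErpError, match="degenerate"):
            paired_ttest(x, x)

    def test_type_one_error_calibrated(self):
        """Null differences at n=37: rejection rate 5% (quick version; the
        full 10,000-rep calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(1)
        rejections = sum(
            paired_ttest(rng.normal(size=37), rng.normal(size=37)).p_raw < 0.05
            for _ in range(2000)
        )
        assert abs(rejections / 2000 - 0.05) < 0.015


class TestFdr:
    def brute_force_bh(self, p):
        """Independent step-up oracle from the definition."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_hand_computed_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_uniform_and_singleton_identity(self):
        assert np.allclose(fdr_adjust([0.5] * 6), 0.5)
        assert np.allclose(fdr_adjust([0.123]), [0.123])

    @settings(max_examples=50, deadline=None)
    @given(hst.integers(min_value=1, max_value=20),
           hst.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_step_up(self, m, seed):
        p = np.random.default_rng(seed).uniform(size=m)
        assert np.allclose(fdr_adjust(p), self.brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(MotionErpError):
            fdr_adjust([0.5, 1.2])


class TestWorkedExamples:
    """The printed statistics that pin down the conventions."""

    @pytest.mark.parametrize("t,d", [
        (-14.19, -2.33), (-13.03, -2.14), (-4.91, -0.80), (6.34, 1.04),
    ])
    def test_cohens_d_from_printed_t(self, t, d):
        assert cohens_d_from_t(t, 37) == pytest.approx(d, abs=0.01)

    @pytest.mark.parametrize("f,r2adj", [(161.42, 0.90), (88.66, 0.83)])
    def test_adjusted_r2_from_printed_f(self, f, r2adj):
        assert r2_adjusted_from_f(f, 2, 37) == pytest.approx(r2adj, abs=0.005)


class TestScreening:
    def test_exact_linear_r_one(self):
        x = np.arange(10.0)
        pred = pd.DataFrame({"x": x})
        out = pd.DataFrame({"y": 2 * x + 1, "z": -x})
        results, screened, dropped = pearson_screen(pred, out)
        rs = {r.outcome: r.r for r in results}
        assert rs["y"] == pytest.approx(1.0)
        assert rs["z"] == pytest.approx(-1.0)
        assert screened == ["x"]

    def test_constant_predictor_dropped(self):
        pred = pd.DataFrame({"c": np.ones(10), "x": np.arange(10.0)})
        out = pd.DataFrame({"y": np.random.default_rng(0).normal(size=10)})
        _, screened, dropped = pearson_screen(pred, out)
        assert dropped == ["c"]

    def test_null_screening_rate_about_5pct(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 800
        for _ in range(reps):
            pred = pd.DataFrame({"x": rng.normal(size=37)})
            out = pd.DataFrame({"y": rng.normal(size=37)})
            _, screened, _ = pearson_screen(pred, out)
            hits += bool(screened)
        assert abs(hits / reps - 0.05) < 0.02


class TestCollinearity:
    def test_two_correlated_predictors_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=200)
        pred = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        kept, table = check_collinearity(pred)
        assert len(kept) == 1
        dropped_tol = table.loc[~table["kept"], "tolerance"].iloc[0]
        assert dropped_tol == pytest.approx(1 - r**2, abs=1e-9)

    def test_orthogonal_predictors_kept(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 3))
        x -= x.mean(axis=0)
        q, _ = np.linalg.qr(x)
        pred = pd.DataFrame(q, columns=list("abc"))
        kept, table = check_collinearity(pred)
        assert kept == ["a", "b", "c"]
        assert np.allclose(table["tolerance"], 1.0, atol=1e-2)

    def test_duplicated_predictor_dropped(self):
        x = np.random.default_rng(5).normal(size=30)
        pred = pd.DataFrame({"x": x, "x2": x})
        kept, table = check_collinearity(pred)
        assert len(kept) == 1

    def test_single_predictor_tolerance_one(self):
        pred = pd.DataFrame({"x": np.arange(10.0)})
        kept, table = check_collinearity(pred)
        assert kept == ["x"]
        assert table["tolerance"].iloc[0] == 1.0


class TestStepwise:
    def test_exact_fit_r2_one(self):
        x = np.arange(20.0)
        res = stepwise_forward(x.copy(), pd.DataFrame({"x": x}))
        assert res.predictors == ["x"]
        assert res.r2 == pytest.approx(1.0)
        assert res.r2_adjusted == pytest.approx(1.0)

    def test_true_predictors_selected(self):
        rng = np.random.default_rng(6)
        n = 37
        X = pd.DataFrame(rng.normal(size=(n, 4)),
                         columns=["n2", "n2r", "nuis1", "nuis2"])
        y = 0.8 * X["n2"] - 1.0 * X["n2r"] + rng.normal(0, 0.4, n)
        res = stepwise_forward(y.to_numpy(), X)
        assert {"n2", "n2r"} <= set(res.predictors)

    def test_no_predictor_enters_flagged(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        x = rng.normal(size=30)
        # orthogonalize x against y (and the intercept): its partial p is ~1
        yc = y - y.mean()
        x = x - x.mean()
        x = x - (x @ yc) / (yc @ yc) * yc
        res = stepwise_forward(y, pd.DataFrame({"x": x}))
        assert res.flags == ["no-predictor-entered"]
        assert res.predictors == []

    def test_adjusted_r2_closed_form_identity(self):
        rng = np.random.default_rng(8)
        n = 37
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = X["a"] + 0.5 * X["b"] + rng.normal(0, 0.8, n)
        res = stepwise_forward(y.to_numpy(), X)
        k = len(res.predictors)
        assert res.r2_adjusted == pytest.approx(
            r2_adjusted_from_f(res.f_stat, k, n), abs=1e-10)

    def test_step_log_records_candidates(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = 2 * X["a"].to_numpy() + rng.normal(size=40)
        res = stepwise_forward(y, X)
        step1 = [e for e in res.step_log if e["step"] == 1]
        assert {e["candidate"] for e in step1} == {"a", "b", "c"}


class TestDiagnostics:
    def _fit(self, y, X):
        res = stepwise_forward(y, X)
        return res

    def test_dw_near_2_for_iid(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"x": rng.normal(size=1000)})
        y = X["x"].to_numpy() + rng.normal(size=1000)
        res = self._fit(y, X)
        assert abs(res.durbin_watson - 2.0) < 0.15

    def test_dw_near_4_for_alternating(self):
        from motionerp.stats import RegressionResult
        import statsmodels.api as sm
        from statsmodels.stats.stattools import durbin_watson

        resid = np.tile([1.0, -1.0], 250)
        assert durbin_watson(resid) == pytest.approx(4.0, abs=0.02)

    def test_breusch_pagan_detects_heteroskedasticity(self):
        rng = np.random.default_rng(11)
        n = 500
        X = pd.DataFrame({"x": rng.uniform(1, 3, n)})
        y = X["x"].to_numpy() * 2 + rng.normal(size=n) * X["x"].to_numpy() ** 2
        res = self._fit(y, X)
        assert res.breusch_pagan_p < 0.01

    def test_ks_normal_residuals_not_rejected(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        y = X["x"].to_numpy() + rng.normal(size=200)
        res = self._fit(y, X)
        assert res.ks_resid_p > 0.01
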