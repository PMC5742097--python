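import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cinemetrics as cm
from cinemetrics.io_formats import KPI_COLUMNS, ValidationError
from cinemetrics.prediction import DEFAULT_MODELS


def engineered_r2(r2, n, k, seed=0):
    """Dataset whose OLS fit attains the requested R-squared exactly.

    y = sqrt(r2) * p + sqrt(1-r2) * q with p a unit mean-zero vector in the
    predictor column space and q a unit vector orthogonal to [1, X].
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, k))
    xc = x - x.mean(axis=0)
    p = xc @ np.ones(k)
    p /= np.linalg.norm(p)
    basis = np.column_stack([np.ones(n) / np.sqrt(n), np.linalg.qr(xc)[0]])
    q = rng.standard_normal(n)
    q -= basis @ (basis.T @ q)
    q /= np.linalg.norm(q)
    y = np.sqrt(r2) * p + np.sqrt(1.0 - r2) * q
    return x, y


class TestFitLinearModel:
    def test_exact_linear_relation(self):
        x = np.arange(5.0)
        res = cm.fit_linear_model(x, 2.0 * x)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.coefficients, [0.0, 2.0], atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        x = np.arange(1.0, 7.0)
        y = np.array([2.0, 1, 4, 3, 6, 5])
        res = cm.fit_linear_model(x, y)
        xc = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(xc.T @ xc, xc.T @ y)
        resid = y - xc @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        np.testing.assert_allclose(res.coefficients, beta, atol=1e-10)

    def test_f_identity_at_r2_049(self):
        x, y = engineered_r2(0.49, n=14, k=1)
        res = cm.fit_linear_model(x, y)
        assert res.r2 == pytest.approx(0.49, abs=1e-12)
        assert res.df == (1, 12)
        assert res.F == pytest.approx(11.53, abs=0.005)

    def test_adjusted_r2_identity_bivariate(self):
        x, y = engineered_r2(0.7370, n=14, k=2)
        res = cm.fit_linear_model(x, y)
        assert res.df == (2, 11)
        assert res.r2_adj == pytest.approx(0.69, abs=0.005)

    def test_result_identities_hold(self, rng):
        x = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        res = cm.fit_linear_model(x, y)
        k, df2 = res.df
        assert res.r2_adj == pytest.approx(1 - (1 - res.r2) * (res.n - 1) / df2, abs=1e-10)
        assert res.F == pytest.approx((res.r2 / k) / ((1 - res.r2) / df2), abs=1e-10)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValidationError, match="constant"):
            cm.fit_linear_model(np.ones(8), rng.standard_normal(8))
        with pytest.raises(ValidationError, match="variance"):
            cm.fit_linear_model(rng.standard_normal(8), np.ones(8))
        with pytest.raises(ValidationError, match="too small"):
            cm.fit_linear_model(rng.standard_normal((3, 2)), rng.standard_normal(3))


class TestBootstrapR2SE:
    def test_perfect_linear_data_gives_zero_se(self):
        x = np.arange(10.0)
        assert cm.bootstrap_r2_se(x, 3.0 * x + 1.0, B=200, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12)
        a = cm.bootstrap_r2_se(x, y, B=300, seed=5)
        assert a == cm.bootstrap_r2_se(x, y, B=300, seed=5)
        assert a != cm.bootstrap_r2_se(x, y, B=300, seed=6)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(12)
        y = 0.8 * x + 0.6 * rng.standard_normal(12)
        ours = cm.bootstrap_r2_se(x, y, B=20000, seed=1)
        # independent oracle: vectorised squared-correlation bootstrap
        orng = np.random.default_rng(777)
        idx = orng.integers(0, 12, size=(20000, 12))
        xs, ys = x[idx], y[idx]
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        ok = (xs_c.std(axis=1) > 0) & (ys_c.std(axis=1) > 0)
        r = (xs_c * ys_c).sum(axis=1) / np.sqrt(
            (xs_c**2).sum(axis=1) * (ys_c**2).sum(axis=1)
        )
        oracle = (r[ok] ** 2).std(ddof=1)
        assert ours == pytest.approx(oracle, rel=0.10)

    def test_b_too_small_rejected(self):
        with pytest.raises(ValidationError):
            cm.bootstrap_r2_se(np.arange(6.0), np.arange(6.0), B=1)


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(cm.fdr_adjust([0.03]), [0.03])

    def test_hand_computed_bh(self):
        np.testing.assert_allclose(
            cm.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(cm.fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12))
    def test_order_invariance_and_bounds(self, pvals):
        p = np.array(pvals)
        q = cm.fdr_adjust(p)
        assert np.all((q >= p - 1e-12) & (q <= 1.0 + 1e-12))
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(cm.fdr_adjust(p[perm]), q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            cm.fdr_adjust([0.5, 1.5])


class TestCorrelationScreen:
    def _study(self, cols):
        return pd.DataFrame(cols)

    def test_perfect_correlations(self):
        y = np.arange(10.0)
        study = self._study({"m1": y, "m2": -y, "kpi": y})
        out = cm.correlation_screen(study, ["m1", "m2"], "kpi")
        assert out["r"].tolist() == pytest.approx([1.0, -1.0])

    def test_textbook_formula_oracle(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        out = cm.correlation_screen(self._study({"m": x, "kpi": y}), ["m"], "kpi")
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert out.loc[0, "r"] == pytest.approx(r, abs=1e-12)

    def test_constant_column_reported_missing(self, rng):
        study = self._study({"m": np.ones(8), "kpi": rng.standard_normal(8)})
        out = cm.correlation_screen(study, ["m"], "kpi")
        assert np.isnan(out.loc[0, "r"])


class TestWeekendSweep:
    def _study(self, n=16, seed=0):
        rng = np.random.default_rng(seed)
        data = {"trailer_id": [f"T{i}" for i in range(n)]}
        for col in DEFAULT_MODELS["Att-Asy-1"] + ["asy_v2", "cogn_40_48",
                                                  "cogn_52_60", "cogn_60_70", "cogn_52_70"]:
            data[col] = rng.random(n)
        for col in KPI_COLUMNS:
            data[col] = rng.random(n)
        return pd.DataFrame(data)

    def test_grid_shape_seven_by_nine(self):
        sweep = cm.weekend_sweep(self._study(), B=25)
        grid = cm.sweep_to_grid(sweep)
        assert grid.shape == (7, 9)
        assert list(grid.columns) == KPI_COLUMNS

    def test_metric_equal_to_kpi_gives_r2_one(self):
        study = self._study()
        study["asy_v1"] = study["premiere"]
        sweep = cm.weekend_sweep(study, models={"Att-Asy-1": ["asy_v1"]}, B=25)
        cell = sweep[(sweep.model == "Att-Asy-1") & (sweep.outcome == "premiere")]
        assert cell["r2"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_metric_survives_fdr(self):
        study = self._study(seed=11)
        sweep = cm.weekend_sweep(study, models={"M": ["asy_v1"]}, B=25)
        assert (sweep["p_fdr"] > 0.05).all()

    def test_outlier_rows_excluded(self):
        study = self._study()
        study["outlier"] = [True] + [False] * 15
        sweep = cm.weekend_sweep(study, models={"M": ["asy_v1"]}, B=25)
        assert (sweep["n"] == 15).all()

    def test_missing_model_column_rejected(self):
        with pytest.raises(ValidationError, match="cogn_missing"):
            cm.weekend_sweep(self._study(), models={"M": ["cogn_missing"]}, B=25)

    def test_bivariate_r2_dominates_univariate(self, rng):
        x = rng.standard_normal((14, 2))
        y = rng.standard_normal(14)
        bi = cm.fit_linear_model(x, y).r2
        u1 = cm.fit_linear_model(x[:, 0], y).r2
        u2 = cm.fit_linear_model(x[:, 1], y).r2
        assert bi >= max(u1, u2) - 1e-12
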