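"""Regression harness relating audience-response metrics to box-office KPIs.

Univariate and bivariate OLS with intercept; case-resampling bootstrap
standard errors on R-squared; Benjamini-Hochberg FDR across the nine weekend
outcomes within each model row; and the full model x outcome sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io_formats import Config, KPI_COLUMNS, ValidationError, logger, substream

# predictor sets of the seven sweep models, keyed by study-table column names
DEFAULT_MODELS: dict[str, list[str]] = {
    "Att-Asy-1": ["asy_v1"],
    "Att-Asy-2": ["asy_v2"],
    "Cogn-40-48": ["cogn_40_48"],
    "Cogn-52-60": ["cogn_52_60"],
    "Cogn-60-70": ["cogn_60_70"],
    "Cogn-52-70": ["cogn_52_70"],
    "Att+Cogn": ["asy_v1", "cogn_52_70"],
}


@dataclass
class RegressionResult:
    r2: float
    r2_adj: float
    F: float
    df: tuple[int, int]
    p: float
    coefficients: np.ndarray  # intercept first
    n: int
    bootstrap_se_r2: float | None = None


def _as_matrix(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def fit_linear_model(X, y) -> RegressionResult:
    """OLS with intercept; F, adjusted R2 and p derived from R2 identities."""
    x = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n, k = x.shape
    if n <= k + 1:
        raise ValidationError(f"n={n} too small for k={k} predictors")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValidationError("constant predictor column")
    if np.ptp(yv) == 0:
        raise ValidationError("outcome has zero variance")
    model = sm.OLS(yv, sm.add_constant(x)).fit()
    r2 = float(model.rsquared)
    df2 = n - k - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df2
    if r2 >= 1.0:  # perfect fit: zero residual variance
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (r2 / k) / ((1.0 - r2) / df2)
        p = float(scipy.stats.f.sf(f_stat, k, df2))
    return RegressionResult(
        r2=r2,
        r2_adj=r2_adj,
        F=f_stat,
        df=(k, df2),
        p=p,
        coefficients=np.asarray(model.params),
        n=n,
    )


def _r2_closed_form(x: np.ndarray, yv: np.ndarray) -> float:
    xc = sm.add_constant(x)
    beta, *_ = np.linalg.lstsq(xc, yv, rcond=None)
    resid = yv - xc @ beta
    ss_tot = ((yv - yv.mean()) ** 2).sum()
    return 1.0 - (resid @ resid) / ss_tot


def bootstrap_r2_se(X, y, B: int | None = None, seed: int = 0) -> float:
    """Case-resampling bootstrap SE of R2 (rows = movies).

    Resamples with a constant predictor or constant outcome cannot be fit and
    are redrawn (logged).  Deterministic given the seed.
    """
    cfg = Config()
    b = cfg.bootstrap_b if B is None else B
    if b < 2:
        raise ValidationError("bootstrap needs B >= 2")
    x = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValidationError("bootstrap needs n >= 4")
    rng = substream(seed, "bootstrap_r2")
    r2s = np.empty(b)
    redraws = 0
    for i in range(b):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            xs, ys = x[idx], yv[idx]
            if np.all(np.ptp(xs, axis=0) > 0) and np.ptp(ys) > 0:
                break
            redraws += 1
        else:  # pragma: no cover - would need pathological data
            raise ValidationError("could not draw a non-degenerate resample")
        r2s[i] = _r2_closed_form(xs, ys)
    if redraws:
        logger.info("bootstrap: redrew %d degenerate resamples", redraws)
    return float(r2s.std(ddof=1))


def bootstrap_slope_ci(
    x, y, B: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the univariate slope (vectorised)."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    n = xv.size
    rng = substream(seed, "bootstrap_slope")
    idx = rng.integers(0, n, size=(B, n))
    xs, ys = xv[idx], yv[idx]
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    var = ((xs - xm) ** 2).sum(axis=1)
    ok = var > 0
    slopes = ((xs - xm) * (ys - ym)).sum(axis=1)[ok] / var[ok]
    alpha = (1 - level) / 2
    lo, hi = np.percentile(slopes, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlation_screen(
    study: pd.DataFrame, metric_cols: list[str], kpi_col: str
) -> pd.DataFrame:
    """Pearson r with two-sided p of each metric column against one KPI column."""
    rows = []
    y = study[kpi_col].to_numpy(dtype=float)
    if y.size < 3:
        raise ValidationError("need at least 3 paired observations")
    for col in metric_cols:
        x = study[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("constant column in correlation screen: %s", col)
            rows.append({"metric": col, "r": np.nan, "p": np.nan})
            continue
        r, p = scipy.stats.pearsonr(x, y)
        rows.append({"metric": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def weekend_sweep(
    study: pd.DataFrame,
    models: dict[str, list[str]] | None = None,
    outcomes: list[str] | None = None,
    config: Config | None = None,
    bootstrap_seed: int = 0,
    B: int | None = None,
) -> pd.DataFrame:
    """Fit every model against premiere + eight weekend KPIs.

    Rows flagged ``outlier`` are excluded throughout.  FDR is applied across
    the nine outcomes within each model row.  Returns a tidy frame with
    columns (model, outcome, r2, r2_adj, F, p, p_fdr, se, n).
    """
    cfg = config or Config()
    models = DEFAULT_MODELS if models is None else models
    outcomes = list(KPI_COLUMNS) if outcomes is None else outcomes
    data = study.loc[~study["outlier"]] if "outlier" in study.columns else study
    for label, cols in models.items():
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValidationError(f"model {label!r}: missing columns {missing}")
    rows = []
    for label, cols in models.items():
        x = data[cols].to_numpy(dtype=float)
        pvals = []
        fits = []
        for outcome in outcomes:
            y = data[outcome].to_numpy(dtype=float)
            res = fit_linear_model(x, y)
            res.bootstrap_se_r2 = bootstrap_r2_se(x, y, B=B, seed=bootstrap_seed)
            fits.append(res)
            pvals.append(res.p)
        qvals = fdr_adjust(pvals)
        for outcome, res, q in zip(outcomes, fits, qvals):
            rows.append(
                {
                    "model": label,
                    "outcome": outcome,
                    "r2": res.r2,
                    "r2_adj": res.r2_adj,
                    "F": res.F,
                    "p": res.p,
                    "p_fdr": float(q),
                    "se": res.bootstrap_se_r2,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def sweep_to_grid(sweep: pd.DataFrame, value: str = "r2") -> pd.DataFrame:
    """Pivot the tidy sweep into the model x outcome grid."""
    grid = sweep.pivot(index="model", columns="outcome", values=value)
    order = [m for m in DEFAULT_MODELS if m in grid.index]
    cols = [c for c in KPI_COLUMNS if c in grid.columns]
    return grid.loc[order, cols]
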