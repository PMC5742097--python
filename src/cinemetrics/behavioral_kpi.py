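"""Stated-preference metrics, box-office KPI, and the outlier-exclusion rule.

LM is the mean liking score; WTW and WTR are yes-fractions of the
willingness-to-watch and willingness-to-refer questions, each pooled over
participants and both viewings of a trailer.  The KPI is weekend revenue
divided by production budget (dimensionless).  A movie is excluded as an
outlier when its premiere KPI lies at least four leave-one-out standard
deviations above the mean of the remaining movies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import Config, ValidationError


def behavioral_metrics(responses: pd.DataFrame, config: Config | None = None) -> pd.DataFrame:
    """Per-trailer LM, WTW, WTR pooled over participants and viewings."""
    cfg = config or Config()
    if len(responses) == 0:
        raise ValidationError("empty response table")
    liking = responses["liking"]
    if ((liking < cfg.liking_min) | (liking > cfg.liking_max)).any():
        raise ValidationError(
            f"liking outside [{cfg.liking_min}, {cfg.liking_max}]"
        )
    keys = ["participant", "viewing", "trailer"]
    if responses.duplicated(subset=keys).any():
        raise ValidationError("more than one response row per (participant, viewing, trailer)")

    def yes_fraction(col: pd.Series) -> float:
        return (col.astype(str).str.lower() == "yes").mean()

    grouped = responses.groupby("trailer")
    out = pd.DataFrame(
        {
            "LM": grouped["liking"].mean(),
            "WTW": grouped["wtw"].apply(yes_fraction),
            "WTR": grouped["wtr"].apply(yes_fraction),
        }
    )
    out.index.name = "trailer_id"
    return out.reset_index()


def compute_kpi(revenue: float, budget: float) -> float:
    """Revenue / budget; the budget normalises for marketing capacity."""
    if budget <= 0:
        raise ValidationError("budget must be positive")
    if revenue < 0:
        raise ValidationError("revenue must be non-negative")
    return revenue / budget


def flag_outlier(kpis: np.ndarray | pd.Series, z_thresh: float = 4.0) -> np.ndarray:
    """Leave-one-out high-side outlier mask (True = excluded).

    Value i is excluded iff (kpi_i - mean(others)) / sd(others) >= z_thresh
    with the sample standard deviation (n-1).  If the others have zero spread,
    any value above their mean is excluded; the rule is one-sided, so low
    values are never excluded.
    """
    x = np.asarray(kpis, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 KPI values for the outlier rule")
    mask = np.zeros(x.size, dtype=bool)
    for i in range(x.size):
        others = np.delete(x, i)
        mu = others.mean()
        sd = others.std(ddof=1)
        if sd == 0.0:
            mask[i] = x[i] > mu
        else:
            mask[i] = (x[i] - mu) / sd >= z_thresh
    return mask


def leave_one_out_z(kpis: np.ndarray | pd.Series) -> np.ndarray:
    """The leave-one-out z-score of each value against the remaining ones."""
    x = np.asarray(kpis, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 KPI values")
    z = np.empty(x.size)
    for i in range(x.size):
        others = np.delete(x, i)
        sd = others.std(ddof=1)
        if sd == 0:
            z[i] = 0.0 if x[i] == others.mean() else np.sign(x[i] - others.mean()) * np.inf
        else:
            z[i] = (x[i] - others.mean()) / sd
    return z


def apply_outlier_rule(
    kpi_table: pd.DataFrame, config: Config | None = None
) -> pd.DataFrame:
    """Add an ``outlier`` column from the premiere-KPI rule.

    The exclusion is decided on the premiere column only and propagates to all
    weekend regressions downstream.
    """
    cfg = config or Config()
    out = kpi_table.copy()
    out["outlier"] = flag_outlier(out["premiere"].to_numpy(), cfg.outlier_z)
    return out
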