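"""Cognitive-congruency: cross-viewing correlated-component eigenvalue.

For each trailer and frequency band, a spatial filter w maximises

    w' R12 w / w' (R11 + R22) w

where R11, R22 are the subject-aggregated covariance matrices of band-power
within the first and second viewings and R12 the cross-viewing covariance
(symmetrised).  The optimum is the top generalized eigenpair of
(R12, R11 + R22); the eigenvalue lambda is the metric.  By Cauchy-Schwarz,
|lambda| <= 0.5, with 0.5 attained when the two viewings' filtered power time
courses coincide.  The forward model a = Rbar w / (w' Rbar w),
Rbar = (R11 + R22)/2, maps the filter back to a scalp topography.

Each channel's power time series is mean-centered within its epoch before
products, so constant power offsets do not masquerade as congruency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io_formats import Config, ValidationError, logger
from .spectrotemporal import BandPowerEpoch


@dataclass
class CovarianceSet:
    """Subject-aggregated within- and cross-viewing band-power covariances."""

    R11: np.ndarray
    R22: np.ndarray
    R12: np.ndarray  # stored symmetrized
    n_subjects: int
    n_times: int
    band: tuple[float, float] = (0.0, 0.0)
    trailer_id: str = ""


@dataclass
class CongruencyResult:
    """The metric lambda with its spatial filter and forward-model topography."""

    lam: float
    w: np.ndarray
    a: np.ndarray | None
    band: tuple[float, float] = (0.0, 0.0)
    trailer_id: str = ""
    spectrum: np.ndarray = field(default_factory=lambda: np.empty(0))


def _center_rows(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def viewing_covariances(
    pairs: list[tuple[BandPowerEpoch, BandPowerEpoch]]
) -> CovarianceSet:
    """Aggregate R11, R22 and symmetrised R12 over subjects.

    Each pair holds the two viewings of one subject for the same trailer and
    band; D and T must agree within and across subjects.  Subjects missing a
    viewing should be dropped upstream (a None in a pair is excluded with a
    warning here).
    """
    usable = []
    for pair in pairs:
        x1, x2 = pair
        if x1 is None or x2 is None:
            who = (x1 or x2).subject if (x1 or x2) else "?"
            logger.warning("subject %s missing a viewing; excluded", who)
            continue
        usable.append((x1, x2))
    if not usable:
        raise ValidationError("no subject contributes both viewings")

    d0, t0 = usable[0][0].X.shape
    acc11 = np.zeros((d0, d0))
    acc22 = np.zeros((d0, d0))
    acc12 = np.zeros((d0, d0))
    for x1, x2 in usable:
        if x1.X.shape != (d0, t0) or x2.X.shape != (d0, t0):
            raise ValidationError(
                f"subject {x1.subject!r}: shapes {x1.X.shape} / {x2.X.shape} "
                f"differ from expected {(d0, t0)}"
            )
        a = _center_rows(np.asarray(x1.X, dtype=float))
        b = _center_rows(np.asarray(x2.X, dtype=float))
        acc11 += a @ a.T
        acc22 += b @ b.T
        acc12 += a @ b.T
    norm = 1.0 / (len(usable) * t0)
    r12 = acc12 * norm
    first = usable[0][0]
    return CovarianceSet(
        R11=acc11 * norm,
        R22=acc22 * norm,
        R12=0.5 * (r12 + r12.T),
        n_subjects=len(usable),
        n_times=t0,
        band=first.band,
        trailer_id=first.trailer_id,
    )


def solve_congruency(
    cov: CovarianceSet, shrinkage: float | None = None, config: Config | None = None
) -> CongruencyResult:
    """Top generalized eigenpair of (R12, R11 + R22 + gamma I).

    ``shrinkage`` is the absolute diagonal load gamma; when None it defaults to
    ``shrinkage_scale * trace(R11 + R22) / D`` from the config, which keeps the
    denominator invertible for rank-deficient short recordings.
    """
    cfg = config or Config()
    for name, mat in (("R11", cov.R11), ("R22", cov.R22), ("R12", cov.R12)):
        if not np.all(np.isfinite(mat)):
            raise ValidationError(f"{name} contains non-finite values")
    denom = cov.R11 + cov.R22
    d = denom.shape[0]
    gamma = (
        shrinkage
        if shrinkage is not None
        else cfg.shrinkage_scale * np.trace(denom) / d
    )
    denom = denom + gamma * np.eye(d)
    try:
        scipy.linalg.cholesky(denom)
    except scipy.linalg.LinAlgError as exc:
        raise ValidationError(
            f"R11 + R22 + {gamma:g} I is not positive definite; "
            "increase the shrinkage"
        ) from exc
    vals, vecs = scipy.linalg.eigh(cov.R12, denom)
    idx = int(np.argmax(vals))
    w = vecs[:, idx]
    return CongruencyResult(
        lam=float(vals[idx]),
        w=w,
        a=None,
        band=cov.band,
        trailer_id=cov.trailer_id,
        spectrum=vals,
    )


def forward_model(result: CongruencyResult, cov: CovarianceSet) -> np.ndarray:
    """Scalp topography a = Rbar w / (w' Rbar w), unit-normalised.

    Only the direction of the pattern is identifiable (the filter scale is
    arbitrary), so the result is returned with unit Euclidean norm, which makes
    it invariant to rescaling w.
    """
    rbar = 0.5 * (cov.R11 + cov.R22)
    w = result.w
    denom = float(w @ rbar @ w)
    if denom == 0.0:
        raise ValidationError("w' Rbar w = 0: filter lies in the null space")
    a = (rbar @ w) / denom
    a = a / np.linalg.norm(a)
    result.a = a
    return a


def cognitive_congruency(
    pairs: list[tuple[BandPowerEpoch, BandPowerEpoch]],
    shrinkage: float | None = None,
    config: Config | None = None,
) -> CongruencyResult:
    """Covariances -> eigenpair -> forward model, in one call."""
    cov = viewing_covariances(pairs)
    result = solve_congruency(cov, shrinkage=shrinkage, config=config)
    forward_model(result, cov)
    return result
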