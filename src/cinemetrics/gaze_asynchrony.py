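"""Attentional-asynchrony: permutation-null divergence of gaze scanpaths.

The gaze streams of all viewers of one trailer are cut into 250 ms windows
hopping every 50 ms (80% overlap; 15 samples and hop 3 at 60 Hz).  Within a
window, the pairwise Euclidean distances between time-matched gaze points of
distinct traces measure instantaneous inter-viewer dispersion.  A null
distribution over distances is built by shuffling the window order
independently per trace (destroying time alignment across participants and
viewings) and pooling the recomputed distances over many draws; its central
90% interval [q05, q95] describes dispersion without shared guidance.

A window is *divergent* when at least a fraction (default 30%) of its real
distances fall inside that null interval — i.e. the window looks like the
misaligned null.  Synchronised windows sit below q05.  The metric is the
fraction of classifiable windows labelled divergent, in [0, 1]; high values
mean the stimulus fails to guide attention consistently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Config, GazeTrace, ValidationError, logger

DIVERGENT = "divergent"
NON_DIVERGENT = "non_divergent"
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class GazeWindow:
    """One sliding window across all member traces."""

    window_index: int
    start_ms: float
    positions: np.ndarray  # (P, m, 2) pixels
    valid: np.ndarray  # (P, m) bool
    members: list[tuple[str, int]]  # (participant, viewing) per trace


@dataclass
class NullDistribution:
    """Central interval of the window-shuffled pairwise-distance pool."""

    q_lo: float
    q_hi: float
    n_draws: int
    seed: int
    degenerate: bool = False


@dataclass
class AsynchronyResult:
    score: float
    labels: list[str]
    null: NullDistribution
    n_windows: int = 0
    n_classifiable: int = 0
    window_start_ms: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


def _window_geometry(cfg: Config) -> tuple[int, int]:
    m = int(round(cfg.win_ms * cfg.gaze_rate / 1000.0))
    h = int(round(cfg.hop_ms * cfg.gaze_rate / 1000.0))
    return m, h


def _stack_traces(traces: list[GazeTrace], cfg: Config) -> tuple[np.ndarray, np.ndarray]:
    """Common-grid check and (P, n, 2) / (P, n) stacking."""
    if len(traces) < 2:
        raise ValidationError("need at least 2 gaze traces")
    n = traces[0].n_samples
    step = 1000.0 / cfg.gaze_rate
    for tr in traces:
        if tr.n_samples != n:
            raise ValidationError(
                f"trace ({tr.participant_id}, v{tr.viewing}) has {tr.n_samples} "
                f"samples, expected {n}: inconsistent grids"
            )
        if tr.n_samples >= 2:
            dt = np.diff(tr.time_ms)
            if np.any(np.abs(dt - step) > 0.5 * step):
                raise ValidationError(
                    f"trace ({tr.participant_id}, v{tr.viewing}) is not on a "
                    f"{cfg.gaze_rate:g} Hz grid"
                )
    pos = np.stack([tr.xy for tr in traces])
    val = np.stack([tr.valid for tr in traces])
    return pos, val


def _windowed(pos: np.ndarray, val: np.ndarray, m: int, h: int):
    """(P, W, m, 2) positions and (P, W, m) validity via strided views."""
    n = pos.shape[1]
    if n < m:
        return (
            np.empty((pos.shape[0], 0, m, 2)),
            np.empty((pos.shape[0], 0, m), dtype=bool),
        )
    sw_pos = np.lib.stride_tricks.sliding_window_view(pos, m, axis=1)[:, ::h]
    sw_val = np.lib.stride_tricks.sliding_window_view(val, m, axis=1)[:, ::h]
    # sliding_window_view puts the window axis last: (P, W, 2, m) -> (P, W, m, 2)
    return np.ascontiguousarray(sw_pos.swapaxes(-1, -2)), np.ascontiguousarray(sw_val)


def segment_windows(
    traces: list[GazeTrace], config: Config | None = None
) -> list[GazeWindow]:
    """Tile the traces with 250 ms / 50 ms-hop windows (count floor((n-m)/h)+1)."""
    cfg = config or Config()
    m, h = _window_geometry(cfg)
    pos, val = _stack_traces(traces, cfg)
    wpos, wval = _windowed(pos, val, m, h)
    members = [(tr.participant_id, tr.viewing) for tr in traces]
    return [
        GazeWindow(
            window_index=k,
            start_ms=k * cfg.hop_ms,
            positions=wpos[:, k],
            valid=wval[:, k],
            members=members,
        )
        for k in range(wpos.shape[1])
    ]


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


def pairwise_gaze_distances(
    win: GazeWindow, min_valid_frac: float = 0.5
) -> np.ndarray | None:
    """Euclidean distances between time-matched valid samples of trace pairs.

    A trace enters the window only if at least ``min_valid_frac`` of its
    samples are valid.  Returns None (unclassifiable) with fewer than two
    usable traces.
    """
    usable = np.nonzero(win.valid.mean(axis=1) >= min_valid_frac)[0]
    if usable.size < 2:
        return None
    out = []
    for i, j in itertools.combinations(usable, 2):
        both = win.valid[i] & win.valid[j]
        if both.any():
            diff = win.positions[i][both] - win.positions[j][both]
            out.append(np.hypot(diff[:, 0], diff[:, 1]))
    if not out:
        return None
    return np.concatenate(out)


def _all_pair_distances(
    wpos: np.ndarray, wval: np.ndarray, min_valid_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Distances (n_pairs, W, m) and usability mask for stacked windows."""
    p = wpos.shape[0]
    pairs = np.array(list(itertools.combinations(range(p), 2)))
    usable = wval.mean(axis=2) >= min_valid_frac  # (P, W)
    a, b = pairs[:, 0], pairs[:, 1]
    diff = wpos[a] - wpos[b]  # (n_pairs, W, m, 2)
    dist = np.sqrt((diff * diff).sum(axis=-1))
    mask = wval[a] & wval[b] & (usable[a] & usable[b])[..., None]
    return dist, mask


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def estimate_null_distribution(
    traces: list[GazeTrace],
    n_draws: int | None = None,
    seed: int | None = None,
    config: Config | None = None,
) -> NullDistribution:
    """Pool pairwise distances over window-shuffled copies of the traces.

    Each draw independently permutes the window order of every trace, so that
    distances are taken between time-misaligned windows; the 5th and 95th
    percentiles of the pooled distances bound the central 90% null interval.
    The pool is uniformly subsampled to ``config.max_null_pool`` values
    (quantile error is negligible at that size); deterministic given the seed.
    """
    cfg = config or Config()
    draws = cfg.n_draws if n_draws is None else n_draws
    the_seed = cfg.seed if seed is None else seed
    if draws < 1:
        raise ValidationError("n_draws must be >= 1")
    m, h = _window_geometry(cfg)
    pos, val = _stack_traces(traces, cfg)
    wpos, wval = _windowed(pos, val, m, h)
    p, w = wpos.shape[0], wpos.shape[1]
    if w < 1:
        raise ValidationError("traces are shorter than one window")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(the_seed)))
    per_draw_cap = max(1, cfg.max_null_pool // draws)
    pool: list[np.ndarray] = []
    for _ in range(draws):
        perms = np.stack([rng.permutation(w) for _ in range(p)])
        rows = np.arange(p)[:, None]
        dist, mask = _all_pair_distances(
            wpos[rows, perms], wval[rows, perms], cfg.min_valid_frac
        )
        d = dist[mask]
        if d.size > per_draw_cap:
            d = d[rng.choice(d.size, per_draw_cap, replace=False)]
        pool.append(d)
    pooled = np.concatenate(pool)
    if pooled.size == 0:
        raise ValidationError("no valid pairwise distances in any draw")
    alpha = (1.0 - cfg.ci_level) / 2.0
    q_lo, q_hi = np.percentile(pooled, [100 * alpha, 100 * (1 - alpha)])
    degenerate = bool(q_lo == q_hi)
    return NullDistribution(
        q_lo=float(q_lo),
        q_hi=float(q_hi),
        n_draws=draws,
        seed=the_seed,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# classification and the metric
# ---------------------------------------------------------------------------


def classify_window(
    distances: np.ndarray | None,
    null: NullDistribution,
    frac: float = 0.30,
    rule: str = "inside",
) -> str:
    """Label one window against the null interval.

    ``inside`` (default): divergent when the share of distances inside
    [q_lo, q_hi] is >= frac (the window is consistent with the misaligned
    null).  ``outside`` inverts the region.  A degenerate null (zero-width
    interval) classifies every window non-divergent.
    """
    if distances is None or len(distances) == 0:
        return UNCLASSIFIABLE
    if null.degenerate:
        return NON_DIVERGENT
    d = np.asarray(distances)
    inside = (d >= null.q_lo) & (d <= null.q_hi)
    share = inside.mean() if rule == "inside" else (~inside).mean()
    return DIVERGENT if share >= frac else NON_DIVERGENT


def attentional_asynchrony(
    traces: list[GazeTrace],
    config: Config | None = None,
    viewing: int | None = None,
    seed: int | None = None,
    null: NullDistribution | None = None,
) -> AsynchronyResult:
    """Fraction of classifiable windows labelled divergent, in [0, 1].

    ``viewing`` restricts the trace set to one viewing (the per-viewing
    variants of the metric); with None both viewings pool together.
    """
    cfg = config or Config()
    if viewing is not None:
        traces = [tr for tr in traces if tr.viewing == viewing]
    if len(traces) < 2:
        raise ValidationError("need at least 2 traces covering the trailer")
    if null is None:
        null = estimate_null_distribution(traces, seed=seed, config=cfg)
    windows = segment_windows(traces, cfg)
    labels = [
        classify_window(
            pairwise_gaze_distances(win, cfg.min_valid_frac),
            null,
            frac=cfg.divergent_frac,
            rule=cfg.divergence_rule,
        )
        for win in windows
    ]
    n_class = sum(1 for lab in labels if lab != UNCLASSIFIABLE)
    if n_class == 0:
        raise ValidationError("no classifiable window")
    n_div = sum(1 for lab in labels if lab == DIVERGENT)
    score = n_div / n_class
    logger.debug(
        "asynchrony %.3f over %d/%d classifiable windows", score, n_class, len(labels)
    )
    return AsynchronyResult(
        score=score,
        labels=labels,
        null=null,
        n_windows=len(labels),
        n_classifiable=n_class,
        window_start_ms=np.array([w.start_ms for w in windows]),
    )
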