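"""Synthetic EEG, gaze, behavioral and KPI data with the structure the metrics assume.

The generators emulate the study design — a cohort watching every trailer
twice — at desk scale (defaults: 8 subjects, 6 trailers, 30 s trailers, 8
channels), so the full pipeline runs in seconds:

* EEG: each trailer has one band-limited source time course (an amplitude-
  modulated in-band carrier), identical in both viewings of every subject —
  the trailer "drives" the component — mixed into the channels through a
  fixed random topography and scaled by a per-trailer SNR; channel noise is
  independent per viewing.  Cross-viewing congruency therefore grows with SNR
  and the planted topography is recoverable.
* Gaze: each trailer has a smooth random attractor path; every trace blends
  the attractor (weight rho) with an independent smooth wander (weight 1-rho)
  plus pixel jitter, on the 60 Hz grid with occasional invalid samples.
* Behavior/KPI: premiere KPI is linear in a per-trailer ground-truth metric
  plus Gaussian noise; weekend KPIs decay geometrically; liking is correlated
  across participants through a per-trailer base level.

All randomness flows from one mandatory seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .io_formats import Config, GazeTable, ValidationError, substream
from .eeg_preprocess import Epoch
from .spectrotemporal import BandPowerEpoch, band_power_epoch


@dataclass
class SimConfig:
    """Study-scale simulation parameters; the seed is mandatory."""

    seed: int
    n_subjects: int = 8
    n_trailers: int = 6
    trailer_dur_s: float = 30.0
    n_channels: int = 8
    eeg_rate: float = 256.0
    pad_s: float = 2.0
    source_band: tuple[float, float] = (52.0, 70.0)
    snr_congruency: tuple[float, ...] | None = None  # per trailer, >= 0
    gaze_sync: tuple[float, ...] | None = None  # rho per trailer, in [0, 1]
    gaze_rate: float = 60.0
    gaze_jitter_px: float = 5.0
    gaze_wander_px: float = 150.0
    invalid_rate: float = 0.02
    screen: tuple[int, int] = (1024, 768)
    kpi_intercept: float = 0.4
    kpi_beta: float = 0.5
    kpi_noise_sd: float = 0.05
    kpi_weekend_decay: float = 0.45
    liking_spread: float = 1.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trailers < 1 or self.n_channels < 1:
            raise ValidationError("all sizes must be positive")
        if self.trailer_dur_s <= 0:
            raise ValidationError("trailer duration must be positive")
        if self.snr_congruency is None:
            self.snr_congruency = tuple(
                np.round(np.linspace(0.5, 4.0, self.n_trailers), 4)
            )
        self.snr_congruency = tuple(float(s) for s in self.snr_congruency)
        if len(self.snr_congruency) != self.n_trailers:
            raise ValidationError("need one SNR per trailer")
        if any(s < 0 for s in self.snr_congruency):
            raise ValidationError("snr must be >= 0")
        if self.gaze_sync is None:
            # the divergence rule reacts in the strong-synchrony regime, so
            # the default attractor weights span half-to-full synchrony
            self.gaze_sync = tuple(
                np.round(np.linspace(0.5, 1.0, self.n_trailers), 4)
            )
        self.gaze_sync = tuple(float(r) for r in self.gaze_sync)
        if len(self.gaze_sync) != self.n_trailers:
            raise ValidationError("need one gaze_sync per trailer")
        if any(not 0.0 <= r <= 1.0 for r in self.gaze_sync):
            raise ValidationError("gaze_sync must lie in [0, 1]")
        if self.kpi_noise_sd < 0:
            raise ValidationError("kpi_noise_sd must be >= 0")

    def trailer_ids(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_trailers)]

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class EEGStudy:
    """Simulated paired epochs plus the planted ground truth per trailer."""

    epochs: list[Epoch]
    topographies: dict[str, np.ndarray]
    snr: dict[str, float]

    def pair(self, subject: str, trailer: str) -> tuple[Epoch, Epoch]:
        sel = {
            e.viewing: e
            for e in self.epochs
            if e.participant_id == subject and e.trailer_id == trailer
        }
        return sel[1], sel[2]


def _bandlimited_noise(
    rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _slow_envelope(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Positive, slowly varying (~0.4 Hz) amplitude envelope, mean ~1."""
    sigma = rate / 2.5
    z = scipy.ndimage.gaussian_filter1d(rng.standard_normal(n), sigma)
    z /= z.std()
    return np.clip(1.0 + 0.6 * z, 0.05, None)


def simulate_eeg_study(cfg: SimConfig) -> EEGStudy:
    """Paired first/second-viewing epochs with a planted congruent component."""
    rng = substream(cfg.seed, "eeg")
    n = int(round((cfg.trailer_dur_s + 2 * cfg.pad_s) * cfg.eeg_rate))
    epochs: list[Epoch] = []
    topo: dict[str, np.ndarray] = {}
    snr_map: dict[str, float] = {}
    for t_idx, trailer in enumerate(cfg.trailer_ids()):
        snr = cfg.snr_congruency[t_idx]
        m = rng.standard_normal(cfg.n_channels)
        m /= np.linalg.norm(m)
        topo[trailer] = m
        snr_map[trailer] = snr
        # one source time course per trailer, present in both viewings
        envelope = _slow_envelope(rng, n, cfg.eeg_rate)
        carrier = _bandlimited_noise(rng, n, cfg.eeg_rate, cfg.source_band)
        source = snr * envelope * carrier
        for subject in cfg.subject_ids():
            for viewing in (1, 2):
                noise = np.stack(
                    [
                        _bandlimited_noise(rng, n, cfg.eeg_rate, cfg.source_band)
                        for _ in range(cfg.n_channels)
                    ]
                )
                samples = m[:, None] * source[None, :] + noise
                epochs.append(
                    Epoch(
                        samples=samples,
                        rate=cfg.eeg_rate,
                        t0_offset_ms=-cfg.pad_s * 1000.0,
                        trailer_id=trailer,
                        participant_id=subject,
                        viewing=viewing,
                    )
                )
    return EEGStudy(epochs=epochs, topographies=topo, snr=snr_map)


def band_power_pairs(
    study: EEGStudy,
    trailer: str,
    band: tuple[float, float],
    config: Config | None = None,
) -> list[tuple[BandPowerEpoch, BandPowerEpoch]]:
    """Per-subject (viewing-1, viewing-2) band-power pairs for one trailer."""
    subjects = sorted({e.participant_id for e in study.epochs if e.trailer_id == trailer})
    pairs = []
    for subject in subjects:
        e1, e2 = study.pair(subject, trailer)
        pairs.append(
            (band_power_epoch(e1, band, config), band_power_epoch(e2, band, config))
        )
    return pairs


def _smooth_path(
    rng: np.random.Generator, n: int, rate: float, scale_px: float,
    center: tuple[float, float],
) -> np.ndarray:
    """Smooth 2-D wander (~0.5 s correlation length) around the screen centre."""
    sigma = rate / 2.0
    path = np.empty((n, 2))
    for k in range(2):
        z = scipy.ndimage.gaussian_filter1d(rng.standard_normal(n), sigma)
        path[:, k] = center[k] + scale_px * z / z.std()
    return path


def simulate_gaze_study(cfg: SimConfig) -> GazeTable:
    """60 Hz gaze tables for both viewings with per-trailer shared attractors."""
    rng = substream(cfg.seed, "gaze")
    n = int(round(cfg.trailer_dur_s * cfg.gaze_rate))
    width, height = cfg.screen
    center = (width / 2.0, height / 2.0)
    time_ms = np.arange(n) * (1000.0 / cfg.gaze_rate)
    frames = []
    for t_idx, trailer in enumerate(cfg.trailer_ids()):
        rho = cfg.gaze_sync[t_idx]
        attractor = _smooth_path(rng, n, cfg.gaze_rate, cfg.gaze_wander_px, center)
        for subject in cfg.subject_ids():
            for viewing in (1, 2):
                wander = _smooth_path(
                    rng, n, cfg.gaze_rate, cfg.gaze_wander_px, center
                )
                pos = (
                    rho * attractor
                    + (1.0 - rho) * wander
                    + cfg.gaze_jitter_px * rng.standard_normal((n, 2))
                )
                pos[:, 0] = np.clip(pos[:, 0], 0, width - 1)
                pos[:, 1] = np.clip(pos[:, 1], 0, height - 1)
                valid = rng.random(n) >= cfg.invalid_rate
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": subject,
                            "viewing": viewing,
                            "trailer_id": trailer,
                            "time_ms": time_ms,
                            "x_px": pos[:, 0],
                            "y_px": pos[:, 1],
                            "valid": valid,
                        }
                    )
                )
    return GazeTable(pd.concat(frames, ignore_index=True))


def simulate_behavior_kpi(
    cfg: SimConfig, true_metrics: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Responses and KPI records linearly coupled to per-trailer ground truth.

    premiere = intercept + beta * metric + N(0, sd); weekend KPIs decay
    geometrically with multiplicative log-normal noise; liking is drawn around
    a per-trailer base level (correlated across participants), and the yes/no
    answers follow a logistic link on the individual liking.
    """
    metrics = np.asarray(true_metrics, dtype=float)
    if metrics.size != cfg.n_trailers:
        raise ValidationError("need one true metric value per trailer")
    rng = substream(cfg.seed, "behavior_kpi")
    trailers = cfg.trailer_ids()

    premiere = (
        cfg.kpi_intercept
        + cfg.kpi_beta * metrics
        + cfg.kpi_noise_sd * rng.standard_normal(cfg.n_trailers)
    )
    premiere = np.clip(premiere, 0.0, None)
    kpi = {"trailer_id": trailers, "premiere": premiere}
    level = premiere.copy()
    for j in range(1, 9):
        level = level * cfg.kpi_weekend_decay * np.exp(
            0.1 * rng.standard_normal(cfg.n_trailers)
        )
        kpi[f"wknd{j}"] = level
    kpi_df = pd.DataFrame(kpi)

    spread = np.ptp(metrics)
    z = (metrics - metrics.mean()) / (spread / 2 if spread > 0 else 1.0)
    base = 5.0 + 2.0 * z
    rows = []
    for t_idx, trailer in enumerate(trailers):
        for subject in cfg.subject_ids():
            for viewing in (1, 2):
                liking = int(
                    np.clip(
                        round(base[t_idx] + cfg.liking_spread * rng.standard_normal()),
                        0,
                        10,
                    )
                )
                p_yes = 1.0 / (1.0 + np.exp(-(liking - 5.0) / 2.0))
                rows.append(
                    {
                        "participant": subject,
                        "viewing": viewing,
                        "trailer": trailer,
                        "liking": liking,
                        "wtw": "yes" if rng.random() < p_yes else "no",
                        "wtr": "yes" if rng.random() < p_yes else "no",
                    }
                )
    return pd.DataFrame(rows), kpi_df
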