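"""Continuous EEG conditioning and epoching.

Pipeline order: downsample to 256 Hz -> 1.5 Hz zero-phase high-pass ->
50/100 Hz notches -> average reference.  All filters are applied
forward-backward (zero phase), so band-limited features keep their latency.
Epochs span [-2000 ms, trailer end + 2000 ms] and have the per-channel mean
over the baseline window [-2000, 0) ms removed; the 2 s padding also absorbs
filter transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.signal

from .io_formats import Config, EEGRecording, ValidationError, logger


@dataclass
class Epoch:
    """One trailer presentation: channels x time at 256 samples/s, microvolts."""

    samples: np.ndarray
    rate: float
    t0_offset_ms: float  # time of first sample relative to trailer onset
    trailer_id: str
    participant_id: str
    viewing: int

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def preprocess_continuous(rec: EEGRecording, config: Config | None = None) -> EEGRecording:
    """Condition a continuous recording: resample, high-pass, notch, re-reference.

    Refuses to upsample (input rate must be >= the 256 Hz target) and needs at
    least two channels for the average reference.  Event sample indices are
    rescaled onto the output grid.
    """
    cfg = config or Config()
    target = cfg.eeg_target_rate
    if rec.rate < target:
        raise ValidationError(
            f"input rate {rec.rate} Hz below target {target} Hz; upsampling refused"
        )
    if rec.n_channels < 2:
        raise ValidationError("average reference requires at least 2 channels")

    x = rec.samples
    if rec.rate != target:
        frac = Fraction(target / rec.rate).limit_denominator(1000)
        # polyphase FIR resampling includes the anti-alias low-pass
        x = scipy.signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    factor = target / rec.rate
    events = [(m, int(round(i * factor))) for m, i in rec.events]
    events = [(m, min(i, x.shape[1] - 1)) for m, i in events]

    sos_hp = scipy.signal.butter(
        cfg.highpass_order, cfg.highpass_hz, btype="highpass", fs=target, output="sos"
    )
    # pad by several filter time constants: the defaults (a few samples) leave
    # long edge transients for a 1.5 Hz high-pass and high-Q notches
    pad_hp = min(x.shape[1] - 1, int(3 * target / cfg.highpass_hz))
    x = scipy.signal.sosfiltfilt(sos_hp, x, axis=1, padlen=pad_hp)

    for f0 in cfg.notch_hz:
        b, a = scipy.signal.iirnotch(f0, cfg.notch_q, fs=target)
        pad_notch = min(x.shape[1] - 1, int(3 * target * cfg.notch_q / f0))
        x = scipy.signal.filtfilt(b, a, x, axis=1, padlen=pad_notch)

    x = x - x.mean(axis=0, keepdims=True)  # average reference
    return EEGRecording(x, target, list(rec.channel_labels), events)


def epoch_signal(
    rec: EEGRecording,
    trailer_spans: list[tuple[str, int, int]],
    participant_id: str = "",
    viewing: int = 1,
    pre_ms: float = 2000.0,
    post_ms: float = 2000.0,
) -> list[Epoch]:
    """Cut one epoch per trailer presentation and remove the baseline mean.

    ``trailer_spans`` holds (trailer_id, start_sample, end_sample) on the
    recording's own (preprocessed) sample grid, half-open [start, end).  The
    epoch covers [start - pre, end + post); the per-channel mean over the
    baseline [-pre, 0) ms is subtracted.
    """
    rate = rec.rate
    pre = int(round(pre_ms * rate / 1000.0))
    post = int(round(post_ms * rate / 1000.0))
    epochs = []
    for trailer_id, start, end in trailer_spans:
        if end is None:
            raise ValidationError(f"trailer {trailer_id!r}: missing end marker")
        if end <= start:
            raise ValidationError(f"trailer {trailer_id!r}: end before start")
        lo, hi = start - pre, end + post
        if lo < 0 or hi > rec.n_samples:
            raise ValidationError(
                f"trailer {trailer_id!r}: epoch window [{lo}, {hi}) exceeds "
                f"recording bounds [0, {rec.n_samples})"
            )
        cut = rec.samples[:, lo:hi].copy()
        baseline = cut[:, :pre].mean(axis=1, keepdims=True)
        cut -= baseline
        epochs.append(
            Epoch(
                samples=cut,
                rate=rate,
                t0_offset_ms=-pre_ms,
                trailer_id=trailer_id,
                participant_id=participant_id,
                viewing=viewing,
            )
        )
    logger.debug("epoched %d trailer presentations", len(epochs))
    return epochs


def spans_from_events(
    rec: EEGRecording, start_prefix: str = "start:", end_prefix: str = "end:"
) -> list[tuple[str, int, int]]:
    """Pair start/end markers ("start:<trailer>", "end:<trailer>") into spans."""
    starts = {m[len(start_prefix):]: i for m, i in rec.events if m.startswith(start_prefix)}
    ends = {m[len(end_prefix):]: i for m, i in rec.events if m.startswith(end_prefix)}
    spans = []
    for tid, s in starts.items():
        if tid not in ends:
            raise ValidationError(f"trailer {tid!r}: missing end marker")
        spans.append((tid, s, ends[tid]))
    return spans
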