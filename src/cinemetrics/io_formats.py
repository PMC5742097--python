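"""Readers, writers and domain containers for EEG, gaze, behavioral and KPI data.

EEG recordings are held as a channels x time matrix in microvolts with a
sampling rate, 10/20 channel labels and event markers.  Gaze data live in a
tidy table (one row per sample) and are grouped into per-(participant,
viewing, trailer) traces on demand.  Time is milliseconds from trailer onset
everywhere; sample indexing is 0-based; windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cinemetrics")

GAZE_COLUMNS = [
    "participant_id",
    "viewing",
    "trailer_id",
    "time_ms",
    "x_px",
    "y_px",
    "valid",
]

RESPONSE_COLUMNS = ["participant", "viewing", "trailer", "liking", "wtw", "wtr"]

KPI_COLUMNS = ["premiere"] + [f"wknd{i}" for i in range(1, 9)]


class FormatError(ValueError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant."""


# ---------------------------------------------------------------------------
# configuration & logging
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Analysis configuration with the study defaults.

    Screen geometry defaults to 1024 x 768 pixels (the stimulus display).
    Frequency bands are (f_lo, f_hi) in Hz, inclusive on both edges when
    averaged on the half-Hz wavelet grid.
    """

    # screen geometry (pixels, origin top-left)
    screen_width: int = 1024
    screen_height: int = 768

    # EEG conditioning
    eeg_target_rate: float = 256.0
    highpass_hz: float = 1.5
    highpass_order: int = 4
    notch_hz: tuple[float, ...] = (50.0, 100.0)
    notch_q: float = 30.0
    epoch_pre_ms: float = 2000.0
    epoch_post_ms: float = 2000.0

    # spectro-temporal decomposition
    morlet_cycles: float = 7.0
    freq_lo: float = 1.0
    freq_hi: float = 80.0
    freq_step: float = 0.5
    power_rate: float = 8.0

    # frequency bands (Hz)
    beta_bands: tuple[tuple[float, float], ...] = ((14, 16), (16, 18), (18, 20))
    gamma_bands: tuple[tuple[float, float], ...] = (
        (40, 48),
        (52, 60),
        (60, 70),
        (52, 70),
    )
    combined_model_band: tuple[float, float] = (52, 70)

    # congruency solver
    shrinkage_scale: float = 1e-6

    # gaze asynchrony
    gaze_rate: float = 60.0
    win_ms: float = 250.0
    hop_ms: float = 50.0
    divergent_frac: float = 0.30
    ci_level: float = 0.90
    n_draws: int = 1000
    min_valid_frac: float = 0.5
    divergence_rule: str = "inside"  # "inside" (default) or "outside"
    max_null_pool: int = 2_000_000

    # behavioral / KPI
    liking_min: int = 0
    liking_max: int = 10
    outlier_z: float = 4.0

    # regression harness
    bootstrap_b: int = 2000

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        # YAML has no tuple type; normalise lists back to tuples
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in value
                )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed.

    Every stochastic component draws from ``substream(seed, "<component>")``
    so partial reruns reproduce exactly.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(key,)))
    )


# ---------------------------------------------------------------------------
# EEG recordings
# ---------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG: channels x time, microvolts."""

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a channels x time matrix")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        n = self.samples.shape[1]
        for marker, idx in self.events:
            if not (0 <= idx < n):
                raise ValidationError(
                    f"event {marker!r} at sample {idx} outside [0, {n})"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_eeg_recording(path: str | Path, dialect: str = "matrix_csv") -> EEGRecording:
    """Read an EEG recording.

    ``matrix_csv``: one row per sample, one column per channel, channel labels
    in the header row, and a JSON sidecar ``<file>.json`` holding the sampling
    rate (mandatory) and optional events.  ``edf``/``bdf`` delegate to mne.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "matrix_csv":
        return _read_matrix_csv(path)
    if dialect in ("edf", "bdf"):
        return _read_edf_bdf(path, dialect)
    raise FormatError(f"unknown EEG dialect: {dialect!r}")


def _read_matrix_csv(path: Path) -> EEGRecording:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file (line 1)")
        labels = header.split(",")
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(labels):
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, "
                    f"header declares {len(labels)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"{path}: missing sidecar {sidecar.name} (sampling rate is "
            "mandatory; it is never guessed)"
        )
    meta = json.loads(sidecar.read_text())
    if "rate" not in meta:
        raise FormatError(f"{sidecar}: no 'rate' key")
    events = [(str(m), int(i)) for m, i in meta.get("events", [])]
    samples = np.asarray(rows, dtype=float).T if rows else np.empty((len(labels), 0))
    return EEGRecording(samples, float(meta["rate"]), labels, events)


def _read_edf_bdf(path: Path, dialect: str) -> EEGRecording:
    import mne

    reader = mne.io.read_raw_edf if dialect == "edf" else mne.io.read_raw_bdf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: unreadable {dialect} file: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    events = [
        (str(desc), int(round(onset * raw.info["sfreq"])))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return EEGRecording(data_uv, float(raw.info["sfreq"]), list(raw.ch_names), events)


def write_eeg_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write the matrix_csv dialect (canonical shortest-repr floats).

    read -> write round-trips byte-identically on files this writer produced.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(rec.channel_labels) + "\n")
        for row in rec.samples.T:
            fh.write(",".join(str(float(v)) for v in row) + "\n")
    meta = {"rate": rec.rate, "channel_labels": rec.channel_labels,
            "events": [[m, i] for m, i in rec.events]}
    _sidecar_path(path).write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# gaze tables & traces
# ---------------------------------------------------------------------------


@dataclass
class GazeTrace:
    """One participant x viewing gaze time series for one trailer (pixels)."""

    participant_id: str
    viewing: int
    trailer_id: str
    time_ms: np.ndarray
    xy: np.ndarray  # (n, 2) pixel coordinates, origin top-left
    valid: np.ndarray  # (n,) bool

    @property
    def n_samples(self) -> int:
        return len(self.time_ms)


@dataclass
class GazeTable:
    """Tidy gaze samples; invalid rows carry valid=False, never dropped."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GAZE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"gaze table missing columns: {missing}")
        df = self.df
        bad = ~df["viewing"].isin([1, 2])
        if bad.any():
            raise ValidationError(
                f"viewing outside {{1,2}} in rows {list(df.index[bad][:10])}"
            )
        keys = ["participant_id", "viewing", "trailer_id", "time_ms"]
        dup = df.duplicated(subset=keys)
        if dup.any():
            raise ValidationError(
                f"duplicated (participant,viewing,trailer,time) rows: "
                f"{list(df.index[dup][:10])}"
            )
        group_keys = ["participant_id", "viewing", "trailer_id"]
        for name, grp in df.groupby(group_keys, sort=False):
            t = grp["time_ms"].to_numpy()
            drops = np.nonzero(np.diff(t) < 0)[0]
            if drops.size:
                rows = list(grp.index[drops + 1][:10])
                raise ValidationError(
                    f"non-monotone time within trace {name}: rows {rows}"
                )

    def traces(self) -> list[GazeTrace]:
        """Group rows into traces keyed by (participant, viewing, trailer).

        Row order within each trace is preserved exactly as read.
        """
        out = []
        for (pid, viewing, tid), grp in self.df.groupby(
            ["participant_id", "viewing", "trailer_id"], sort=False
        ):
            out.append(
                GazeTrace(
                    participant_id=str(pid),
                    viewing=int(viewing),
                    trailer_id=str(tid),
                    time_ms=grp["time_ms"].to_numpy(dtype=float),
                    xy=grp[["x_px", "y_px"]].to_numpy(dtype=float),
                    valid=grp["valid"].to_numpy(dtype=bool),
                )
            )
        return out


def read_gaze_table(path: str | Path) -> GazeTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["valid"] = df["valid"].astype(bool)
    df["viewing"] = df["viewing"].astype(int)
    return GazeTable(df[GAZE_COLUMNS].copy())


def write_gaze_table(table: GazeTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = table.df.copy()
    df["valid"] = df["valid"].astype(bool)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# behavioral responses, KPI and study tables
# ---------------------------------------------------------------------------


def read_response_table(path: str | Path) -> pd.DataFrame:
    """Stated-preference responses: liking (integer scale), wtw/wtr yes-no."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df[RESPONSE_COLUMNS].copy()


def read_kpi_table(path: str | Path) -> pd.DataFrame:
    """KPI table: one row per trailer, premiere + eight weekend columns."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in KPI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df[KPI_COLUMNS].to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative KPI values")
    return df


def load_packaged_kpi_table() -> pd.DataFrame:
    """The study's 15-movie box-office KPI table (revenue / budget)."""
    ref = importlib.resources.files("cinemetrics.data").joinpath("kpi_table.csv")
    with importlib.resources.as_file(ref) as p:
        return read_kpi_table(p)


def validate_study_table(df: pd.DataFrame, kpi_columns: Sequence[str] = KPI_COLUMNS) -> pd.DataFrame:
    """Check the per-trailer study table feeding the regression sweep."""
    if "trailer_id" not in df.columns:
        raise ValidationError("study table needs a trailer_id column")
    if df["trailer_id"].duplicated().any():
        raise ValidationError("study table must have exactly one row per trailer")
    for col in kpi_columns:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"negative KPI values in column {col}")
    return df
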