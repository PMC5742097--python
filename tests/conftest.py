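import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cinemetrics as cm
from cinemetrics.io_formats import GazeTrace

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaze_df():
    """Tiny valid gaze table: 2 participants x 2 viewings x 600 samples."""
    rows = []
    rng = np.random.default_rng(0)
    t = np.arange(600) * (1000.0 / 60.0)
    for pid in ("P1", "P2"):
        for viewing in (1, 2):
            x = rng.uniform(0, 1024, 600)
            y = rng.uniform(0, 768, 600)
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "viewing": viewing,
                        "trailer_id": "T1",
                        "time_ms": t,
                        "x_px": x,
                        "y_px": y,
                        "valid": True,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def make_traces(positions, rate=60.0, trailer="T"):
    """Build GazeTraces from a (P, n, 2) array, all samples valid."""
    positions = np.asarray(positions, dtype=float)
    p, n, _ = positions.shape
    t = np.arange(n) * (1000.0 / rate)
    return [
        GazeTrace(f"P{i}", 1, trailer, t, positions[i], np.ones(n, dtype=bool))
        for i in range(p)
    ]


@pytest.fixture
def uniform_traces():
    """12 i.i.d.-uniform gaze traces over a 20 s trailer."""
    rng = np.random.default_rng(7)
    pos = rng.uniform([0, 0], [1024, 768], size=(12, 1200, 2))
    return make_traces(pos)


@pytest.fixture
def band_power_pair_factory():
    """Planted-component band-power pairs at a given SNR (no wavelets)."""

    def factory(snr, n_subjects=6, d=4, t=600, seed=0):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal(d)
        m /= np.linalg.norm(m)
        shared = rng.gamma(2.0, 1.0, size=t)  # positive shared power course
        pairs = []
        for s in range(n_subjects):
            def one(viewing):
                noise = rng.gamma(2.0, 1.0, size=(d, t))
                x = snr * np.abs(m[:, None]) * shared[None, :] + noise
                return cm.BandPowerEpoch(X=x, band=(52, 70), subject=f"S{s}", viewing=viewing)
            pairs.append((one(1), one(2)))
        return pairs, np.abs(m)

    return factory
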