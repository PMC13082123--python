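"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gliowave import AnalysisConfig, SimConfig
from gliowave.config import NullConfig


def brute_lag_pearson(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Independent oracle: naive per-lag Pearson on the overlapping samples.

    Deliberately written as a plain loop over lags using numpy.corrcoef so it
    shares no code path with the FFT implementation it checks.
    """
    n = len(x)
    out = np.empty(2 * max_lag + 1)
    for i, tau in enumerate(range(-max_lag, max_lag + 1)):
        if tau >= 0:
            xs, ys = x[: n - tau], y[tau:]
        else:
            xs, ys = x[-tau:], y[: n + tau]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(xs, ys)[0, 1]
    return out


@pytest.fixture
def brute_oracle():
    return brute_lag_pearson


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_cfg():
    """A compact field for fast pipeline-level tests: 3-min recording at
    20 Hz, 20 cells, 4 couplings."""
    return SimConfig(n_cells=20, field_um=250.0, frame_rate=20.0,
                     duration_s=180.0, n_sources=4, n_edges=4,
                     source_period_s=15.0, background_rate_per_min=0.5,
                     seed=7)


@pytest.fixture
def small_analysis_cfg():
    """Analysis parameters matched to the compact field (short surrogate
    floor so the 3-min recording supports a null model)."""
    cfg = AnalysisConfig()
    cfg.null = NullConfig(n_surrogates_per_pair=10, dt_min_s=60.0)
    return cfg


@pytest.fixture
def toy_roi_table():
    return pd.DataFrame({"cell_id": ["a", "b", "c"],
                         "x": [0.0, 30.0, 0.0],
                         "y": [0.0, 0.0, 40.0]})
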