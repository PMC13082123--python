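"""ΔF/F normalisation, calcium peak detection and activity gating.

The analysis unit downstream is the calcium peak: a cell is "active" (and
enters the network analysis) only if its trace carries at least
``active_min_peaks`` peaks (default 4) over the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import BaselineConfig, PeakConfig

logger = logging.getLogger("gliowave.traces")

__all__ = ["TraceMatrix", "DffTrace", "PeakSet", "compute_dff",
           "detect_peaks", "event_rate", "robust_noise_scale"]


@dataclass
class TraceMatrix:
    """Raw per-cell fluorescence, frames × cells, with its sampling rate."""

    values: np.ndarray          # (n_frames, n_cells), arbitrary units
    frame_rate: float           # Hz
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be frames × cells")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.values.shape[1] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match values")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("trace matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class DffTrace:
    """Normalised calcium signal ΔF/F = (F − F0)/F0 with its F0 estimate.

    Cells whose F0 estimate is non-positive cannot be normalised; they are
    flagged invalid (``valid = False``), their dff column is zeroed, and they
    are excluded downstream.
    """

    dff: np.ndarray             # (n_frames, n_cells), dimensionless
    f0: np.ndarray              # per cell, raw units
    frame_rate: float
    cell_ids: list[str]
    valid: np.ndarray = field(default=None)  # bool per cell

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.dff.shape[1], dtype=bool)
        if not np.isfinite(self.dff).all():
            raise ValueError("dff contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class PeakSet:
    """Detected calcium peaks and the per-cell activity verdict."""

    cell_ids: list[str]
    peak_times: list[np.ndarray]        # s, sorted, one array per cell
    prominences: list[np.ndarray]
    is_active: np.ndarray               # bool per cell
    duration_s: float
    active_min_peaks: int = 4

    @property
    def peak_count(self) -> np.ndarray:
        return np.array([len(t) for t in self.peak_times], dtype=int)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def counts_by_id(self) -> dict[str, int]:
        return dict(zip(self.cell_ids, self.peak_count.tolist()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, times, prom in zip(self.cell_ids, self.peak_times,
                                    self.prominences):
            for t, p in zip(times, prom):
                rows.append((cid, t, p))
        return pd.DataFrame(rows, columns=["cell_id", "peak_time_s",
                                           "prominence"])

    def activity_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids,
                             "n_peaks": self.peak_count,
                             "is_active": self.is_active})


def _percentile_baseline(values: np.ndarray, cfg: BaselineConfig,
                         frame_rate: float) -> np.ndarray:
    """F0 per cell (global) or per frame × cell (rolling)."""
    w = int(round(cfg.presmooth_s * frame_rate))
    if w > 1:
        kernel = np.ones(w) / w
        values = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, values)
    if cfg.method == "global-percentile":
        return np.percentile(values, cfg.q, axis=0)
    # rolling percentile, centered, min_periods=1 so edges stay defined
    window = max(int(round(cfg.window_s * frame_rate)), 1)
    df = pd.DataFrame(values)
    f0 = df.rolling(window, center=True, min_periods=1).quantile(cfg.q / 100.0)
    return f0.to_numpy()


def compute_dff(raw: TraceMatrix, baseline: BaselineConfig | None = None,
                background: np.ndarray | None = None) -> DffTrace:
    """Normalise raw fluorescence to ΔF/F = (F − F0)/F0.

    ``background``, if given, is a per-frame background trace subtracted from
    every cell before F0 estimation.  Cells with non-positive F0 (e.g. an
    all-zero trace) are flagged invalid rather than raising.
    """
    baseline = baseline or BaselineConfig()
    values = raw.values
    if background is not None:
        background = np.asarray(background, dtype=float).reshape(-1, 1)
        if background.shape[0] != raw.n_frames:
            raise ValueError("background length must match frame count")
        values = values - background

    f0 = _percentile_baseline(values, baseline, raw.frame_rate)
    f0_per_cell = f0 if f0.ndim == 1 else np.nanmin(f0, axis=0)
    valid = f0_per_cell > 0

    dff = np.zeros_like(values)
    if f0.ndim == 1:
        np.divide(values - f0, f0, out=dff, where=valid[np.newaxis, :])
    else:
        np.divide(values - f0, f0, out=dff,
                  where=valid[np.newaxis, :] & (f0 > 0))
    dff[:, ~valid] = 0.0

    n_bad = int((~valid).sum())
    if n_bad:
        bad = [cid for cid, ok in zip(raw.cell_ids, valid) if not ok]
        logger.warning("%d cell(s) with non-positive F0 flagged invalid: %s",
                       n_bad, ", ".join(bad[:10]))
    return DffTrace(dff=dff, f0=np.atleast_1d(f0_per_cell),
                    frame_rate=raw.frame_rate, cell_ids=list(raw.cell_ids),
                    valid=valid)


def robust_noise_scale(dff_col: np.ndarray) -> float:
    """Per-cell noise σ̂ = 1.4826 × MAD(diff(dff)) / √2.

    The first difference removes slow signal components; the √2 corrects for
    differencing doubling the noise variance.
    """
    d = np.diff(dff_col)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(dff: DffTrace, cfg: PeakConfig | None = None) -> PeakSet:
    """Prominence-gated local maxima of ΔF/F, with the ≥4-peak activity rule.

    A flat or invalid trace yields zero peaks and an inactive verdict; that is
    a normal outcome, not an error.
    """
    cfg = cfg or PeakConfig()
    distance = max(int(round(cfg.min_separation_s * dff.frame_rate)), 1)
    window = int(round(cfg.smooth_s * dff.frame_rate))
    kernel = np.ones(window) / window if window > 1 else None
    peak_times: list[np.ndarray] = []
    prominences: list[np.ndarray] = []
    for j in range(dff.dff.shape[1]):
        col = dff.dff[:, j]
        if not dff.valid[j]:
            peak_times.append(np.empty(0))
            prominences.append(np.empty(0))
            continue
        sigma = robust_noise_scale(col)
        threshold = max(cfg.k * sigma, 1e-12)
        sm = np.convolve(col, kernel, mode="same") if kernel is not None else col
        idx, props = find_peaks(sm, prominence=threshold, distance=distance)
        peak_times.append(idx / dff.frame_rate)
        prominences.append(props["prominences"])
    counts = np.array([len(t) for t in peak_times])
    is_active = counts >= cfg.active_min_peaks
    return PeakSet(cell_ids=list(dff.cell_ids), peak_times=peak_times,
                   prominences=prominences, is_active=is_active,
                   duration_s=dff.duration_s,
                   active_min_peaks=cfg.active_min_peaks)


def event_rate(peaks: "PeakSet | int", duration_s: float,
               n_cells: int | None = None) -> float:
    """Population event rate in calcium peaks · min⁻¹ · (100 cells)⁻¹.

    ``peaks`` may be a PeakSet or a precomputed total peak count.
    """
    if isinstance(peaks, PeakSet):
        total = int(peaks.peak_count.sum())
        if n_cells is None:
            n_cells = peaks.n_cells
    else:
        total = int(peaks)
        if n_cells is None:
            raise ValueError("n_cells required when passing a raw count")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if n_cells < 1:
        raise ValueError("empty cell population")
    return total / (duration_s / 60.0) / (n_cells / 100.0)
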