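"""Linear-shift surrogate null model for co-activity significance.

For each gate-passing pair, one trace is time-shifted by a large random
offset ΔT (> 5 min by default), which preserves each trace's temporal
autocorrelation while destroying any cross-cell coupling.  The maximal
lagged correlation of many such surrogate pairs, pooled over pairs and
draws, forms the null distribution; its 95th percentile is the significance
threshold r0 for calling an edge.

The shift is circular (wrap-around) by default: with 10-min recordings and
ΔT > 5 min a truncating shift would discard more than half of the data,
whereas the circular rotation keeps length, mean, variance and
autocorrelation structure exactly.  A truncating variant is available via
``NullConfig.mode = "truncate"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import GateConfig, NullConfig
from .coactivity import LagEngine, PairStat
from .traces import DffTrace

logger = logging.getLogger("gliowave.nullmodel")

__all__ = ["NullModel", "linear_shift", "build_null",
           "significance_threshold"]


@dataclass
class NullModel:
    """Pooled surrogate connectivity strengths and the derived threshold."""

    surrogate_r: np.ndarray             # pooled r_max values
    percentile: float
    n_surrogates_per_pair: int
    n_pairs: int
    seed: int
    per_pair_r: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def threshold_r0(self) -> float:
        return significance_threshold(self)

    def summary(self) -> dict:
        return {"percentile": self.percentile,
                "threshold_r0": self.threshold_r0,
                "n_pairs": self.n_pairs,
                "n_surrogates_per_pair": self.n_surrogates_per_pair,
                "seed": self.seed,
                "n_pooled": int(self.surrogate_r.size)}


def linear_shift(trace: np.ndarray, shift_frames: int) -> np.ndarray:
    """Circularly rotate a series by ``shift_frames`` (0 ≤ shift < n).

    The rotated series has exactly the same multiset of values, mean,
    variance and autocorrelation structure as the original.
    """
    trace = np.asarray(trace)
    n = trace.shape[0]
    if not 0 <= shift_frames < n:
        raise ValueError(f"shift must satisfy 0 <= shift < {n}")
    return np.roll(trace, shift_frames, axis=0)


def _shift_range_frames(n_frames: int, frame_rate: float,
                        dt_min_s: float) -> tuple[int, int]:
    """Valid surrogate shifts in frames: ΔT ∈ (dt_min, T), exclusive."""
    duration = n_frames / frame_rate
    if duration <= dt_min_s:
        raise ValueError(
            f"recording ({duration:.1f} s) too short for the null model "
            f"(needs duration > ΔT_min = {dt_min_s:.0f} s)")
    lo = int(np.floor(dt_min_s * frame_rate)) + 1
    hi = n_frames - 1                      # inclusive
    if lo > hi:
        raise ValueError("no admissible surrogate shifts for this recording")
    return lo, hi


def build_null(dff: DffTrace, pairs: list[PairStat],
               cfg: NullConfig | None = None,
               gates: GateConfig | None = None,
               seed: int = 0,
               max_lag_frames: int | None = None,
               engine: LagEngine | None = None) -> NullModel:
    """Surrogate r_max distribution over the gate-passing pairs.

    For every passing pair and each of ``n_surrogates_per_pair`` draws, the
    second trace is shifted by an independent uniform random ΔT ∈ (ΔT_min, T)
    and the maximal lagged correlation recomputed on the same lag grid as the
    observed statistic.  All values are pooled (per-pair distributions are
    retained when ``cfg.pooling == "per_pair"``).
    """
    cfg = cfg or NullConfig()
    gates = gates or GateConfig()
    passing = [p for p in pairs if p.verdict == "pass"]
    if not passing:
        raise ValueError("no gate-passing pairs: cannot build a null model")

    if max_lag_frames is None:
        max_lag_frames = int(np.ceil(dff.frame_rate
                                     * gates.resolved_max_lag_s()))
    max_lag_frames = min(max_lag_frames, dff.n_frames - 3)
    if engine is None:
        engine = LagEngine(dff.dff, max_lag_frames, dff.frame_rate)

    lo, hi = _shift_range_frames(dff.n_frames, dff.frame_rate, cfg.dt_min_s)
    rng = np.random.default_rng(seed)
    index = {cid: k for k, cid in enumerate(dff.cell_ids)}

    pooled: list[float] = []
    per_pair: dict[tuple[str, str], np.ndarray] = {}
    for p in passing:
        i, j = index[p.cell_a], index[p.cell_b]
        shifts = rng.integers(lo, hi + 1, size=cfg.n_surrogates_per_pair)
        vals = np.empty(cfg.n_surrogates_per_pair)
        for k, s in enumerate(shifts):
            if cfg.mode == "circular":
                vals[k] = engine.r_max(i, j, shift_j=int(s))
            else:
                vals[k] = _truncated_rmax(dff, i, j, int(s), max_lag_frames)
        vals = vals[~np.isnan(vals)]
        if cfg.pooling == "per_pair":
            per_pair[(p.cell_a, p.cell_b)] = vals
        pooled.append(vals)

    surrogate_r = np.concatenate(pooled) if pooled else np.empty(0)
    logger.info("null model: %d pairs × %d surrogates → %d pooled values",
                len(passing), cfg.n_surrogates_per_pair, surrogate_r.size)
    return NullModel(surrogate_r=surrogate_r, percentile=cfg.percentile,
                     n_surrogates_per_pair=cfg.n_surrogates_per_pair,
                     n_pairs=len(passing), seed=seed, per_pair_r=per_pair)


def _truncated_rmax(dff: DffTrace, i: int, j: int, shift: int,
                    max_lag_frames: int) -> float:
    """Non-wrapping shift variant: correlate the overlapping tail/head."""
    n = dff.n_frames
    x = dff.dff[shift:, i]
    y = dff.dff[: n - shift, j]
    L = min(max_lag_frames, len(x) - 3)
    if L < 0:
        return float("nan")
    eng = LagEngine(np.column_stack([x, y]), L, dff.frame_rate)
    return eng.r_max(0, 1)


def significance_threshold(null: NullModel,
                           percentile: float | None = None) -> float:
    """Percentile of the pooled surrogate distribution (linear interpolation).

    This is numpy's default ``linear`` percentile definition; the same rule
    is used for the hub-degree quantile so the two cutoffs are consistent.
    """
    if null.surrogate_r.size == 0:
        raise ValueError("null model has no surrogate values")
    q = null.percentile if percentile is None else percentile
    return float(np.percentile(null.surrogate_r, q))
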