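"""Time-lagged pairwise correlation, propagation velocity and pair gating.

Connectivity strength between two cells is the maximum Pearson correlation of
their ΔF/F traces across integer frame lags; the lag at the maximum, combined
with the centroid distance, yields the implied signal propagation speed.
Pairs are then gated physiologically: distance ≤ 100 μm, speed within
[4, 25] μm/s, and at least 4 calcium peaks in each cell.

The per-lag Pearson correlation uses only the overlapping samples at each
lag, each lag normalised by its own overlap means and variances (no
zero-padding).  Cross-products are computed by FFT so that the full ±max_lag
grid on 10-min, 40-Hz recordings stays fast; the result is algebraically
identical to a naive per-lag loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft

from .config import GateConfig, PeakConfig
from .traces import DffTrace, PeakSet

logger = logging.getLogger("gliowave.coactivity")

__all__ = ["LagCorrelation", "PairStat", "LagEngine", "lagged_correlation",
           "propagation_speed", "pair_filter", "all_pairs", "pair_frame",
           "distance_um"]

#: speed reported when the best lag is exactly zero (division by zero);
#: downstream the sentinel always fails the speed window.
SPEED_UNDEFINED = float("nan")


@dataclass
class LagCorrelation:
    """Per-lag Pearson correlation and its maximum."""

    lags: np.ndarray            # frame lags, -L..L
    r: np.ndarray               # correlation per lag; NaN where undefined
    r_max: float                # NaN when every lag is undefined
    best_lag: int | None        # frames; None when every lag is undefined
    frame_rate: float

    @property
    def best_lag_s(self) -> float | None:
        return None if self.best_lag is None else self.best_lag / self.frame_rate


@dataclass
class PairStat:
    """One unordered cell pair's co-activity statistics and filter verdict."""

    cell_a: str
    cell_b: str
    distance_um: float
    r_max: float
    best_lag_s: float | None
    speed_um_s: float           # NaN sentinel when best lag is 0 or undefined
    verdict: str = "unfiltered"     # "pass" | "excluded"
    reason: str = ""                # "distance" | "speed" | "inactivity"
    r_by_lag: np.ndarray | None = None
    lags_s: np.ndarray | None = None


def _pick_best_lag(lags: np.ndarray, r: np.ndarray) -> tuple[float, int | None]:
    """Max r with ties broken toward the smallest |lag|, then negative lag."""
    if np.all(np.isnan(r)):
        return float("nan"), None
    r_max = float(np.nanmax(r))
    # ties are resolved within a float tolerance so that exact analytic ties
    # (e.g. periodic signals) are not split by rounding
    with np.errstate(invalid="ignore"):
        cand = lags[r >= r_max - 1e-9]
    order = np.lexsort((cand, np.abs(cand)))
    return r_max, int(cand[order[0]])


class LagEngine:
    """Cached per-trace FFTs and cumulative sums for fast per-lag Pearson.

    Traces are globally mean-centred up front (Pearson is shift-invariant per
    overlap, and centring avoids cancellation in the FFT cross-products).
    """

    def __init__(self, traces: np.ndarray, max_lag_frames: int,
                 frame_rate: float):
        traces = np.asarray(traces, dtype=float)
        if traces.ndim != 2:
            raise ValueError("traces must be frames × cells")
        n = traces.shape[0]
        if not 0 <= max_lag_frames <= n - 3:
            raise ValueError("need 0 <= max_lag_frames <= n_frames - 3 "
                             "(>=3 overlapping samples at the extreme lag)")
        self.n = n
        self.L = int(max_lag_frames)
        self.frame_rate = frame_rate
        self.lags = np.arange(-self.L, self.L + 1)
        self._abs_lags = np.abs(self.lags)
        self._m = (n - self._abs_lags).astype(float)
        self.nfft = next_fast_len(2 * n - 1)
        xc = traces - traces.mean(axis=0, keepdims=True)
        self._xc = xc
        self._spec = rfft(xc, n=self.nfft, axis=0)
        self._cum1 = np.vstack([np.zeros((1, xc.shape[1])), np.cumsum(xc, axis=0)])
        self._cum2 = np.vstack([np.zeros((1, xc.shape[1])),
                                np.cumsum(xc * xc, axis=0)])
        # per-trace variance floor below which an overlap is called constant
        self._ss = self._cum2[-1]

    def _parts(self, j: int, shift: int | None):
        """(spectrum, cum1, cum2, total SS) of trace j, optionally rotated."""
        if shift is None:
            return (self._spec[:, j], self._cum1[:, j], self._cum2[:, j],
                    self._ss[j])
        z = np.roll(self._xc[:, j], shift)
        c1 = np.concatenate(([0.0], np.cumsum(z)))
        c2 = np.concatenate(([0.0], np.cumsum(z * z)))
        return rfft(z, n=self.nfft), c1, c2, self._ss[j]

    def r_by_lag(self, i: int, j: int, shift_j: int | None = None) -> np.ndarray:
        """Pearson r(τ) of (x_i[t], x_j[t+τ]) for τ in -L..L.

        ``shift_j`` circularly rotates trace j before correlating (used by the
        surrogate null).  Lags whose overlap has (numerically) zero variance
        in either trace are NaN.
        """
        n, L = self.n, self.L
        Fi, c1i, c2i, ssi = self._parts(i, None)
        Fj, c1j, c2j, ssj = self._parts(j, shift_j)
        cc = irfft(np.conj(Fi) * Fj, n=self.nfft)
        sxy = cc[self.lags % self.nfft]

        pos = self.lags >= 0
        tau = self.lags
        # x-segment: [0, n-τ) for τ>=0, [-τ, n) for τ<0
        sx = np.where(pos, c1i[np.clip(n - tau, 0, n)],
                      c1i[n] - c1i[np.clip(-tau, 0, n)])
        sxx = np.where(pos, c2i[np.clip(n - tau, 0, n)],
                       c2i[n] - c2i[np.clip(-tau, 0, n)])
        # y-segment: [τ, n) for τ>=0, [0, n+τ) for τ<0
        sy = np.where(pos, c1j[n] - c1j[np.clip(tau, 0, n)],
                      c1j[np.clip(n + tau, 0, n)])
        syy = np.where(pos, c2j[n] - c2j[np.clip(tau, 0, n)],
                       c2j[np.clip(n + tau, 0, n)])

        m = self._m
        cov = sxy - sx * sy / m
        vx = sxx - sx * sx / m
        vy = syy - sy * sy / m
        eps_x = 1e-12 * ssi / n * m + 1e-300
        eps_y = 1e-12 * ssj / n * m + 1e-300
        ok = (vx > eps_x) & (vy > eps_y)
        r = np.full(self.lags.shape, np.nan)
        denom = np.sqrt(vx[ok] * vy[ok])
        r[ok] = np.clip(cov[ok] / denom, -1.0, 1.0)
        return r

    def correlate(self, i: int, j: int,
                  shift_j: int | None = None) -> LagCorrelation:
        r = self.r_by_lag(i, j, shift_j)
        r_max, best = _pick_best_lag(self.lags, r)
        return LagCorrelation(lags=self.lags.copy(), r=r, r_max=r_max,
                              best_lag=best, frame_rate=self.frame_rate)

    def r_max(self, i: int, j: int, shift_j: int | None = None) -> float:
        r = self.r_by_lag(i, j, shift_j)
        if np.all(np.isnan(r)):
            return float("nan")
        return float(np.nanmax(r))


def lagged_correlation(x: np.ndarray, y: np.ndarray, max_lag_frames: int,
                       frame_rate: float = 1.0) -> LagCorrelation:
    """Per-lag Pearson correlation of two equal-length series.

    A positive best lag means ``y`` lags (is delayed relative to) ``x``.
    Ties in the maximum are broken toward the smallest |lag|, then toward the
    negative lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    eng = LagEngine(np.column_stack([x, y]), max_lag_frames, frame_rate)
    return eng.correlate(0, 1)


def propagation_speed(distance_um: float, best_lag_s: float | None) -> float:
    """Implied propagation speed d/|τ*| in μm/s.

    A zero (or undefined) lag returns the undefined-speed sentinel (NaN),
    which downstream always fails the speed window.
    """
    if distance_um < 0:
        raise ValueError("distance must be non-negative")
    if best_lag_s is None or best_lag_s == 0:
        return SPEED_UNDEFINED
    return distance_um / abs(best_lag_s)


def distance_um(rois: pd.DataFrame, cell_a: str, cell_b: str) -> float:
    """Euclidean centroid distance between two cells in the ROI table."""
    t = rois.set_index("cell_id") if "cell_id" in rois.columns else rois
    dx = t.loc[cell_a, "x"] - t.loc[cell_b, "x"]
    dy = t.loc[cell_a, "y"] - t.loc[cell_b, "y"]
    return float(math.hypot(dx, dy))


def pair_filter(p: PairStat, peak_counts: dict[str, int],
                gates: GateConfig | None = None,
                peaks_cfg: PeakConfig | None = None) -> PairStat:
    """Apply the physiological exclusion gates, recording the first violation.

    Order: (1) distance > d_max; (2) speed outside the closed window
    [v_min, v_max] (an undefined/zero-lag speed also fails); (3) either cell
    below the activity gate.  A pair whose correlation is undefined at every
    lag is excluded as inactive.
    """
    gates = gates or GateConfig()
    min_peaks = (peaks_cfg or PeakConfig()).active_min_peaks
    if p.distance_um > gates.d_max_um:
        return replace(p, verdict="excluded", reason="distance")
    if p.best_lag_s is None or math.isnan(p.r_max):
        return replace(p, verdict="excluded", reason="inactivity")
    v = p.speed_um_s
    if math.isnan(v) or not (gates.v_min_um_s <= v <= gates.v_max_um_s):
        return replace(p, verdict="excluded", reason="speed")
    if (peak_counts.get(p.cell_a, 0) < min_peaks
            or peak_counts.get(p.cell_b, 0) < min_peaks):
        return replace(p, verdict="excluded", reason="inactivity")
    return replace(p, verdict="pass", reason="")


def all_pairs(dff: DffTrace, rois: pd.DataFrame, peaks: PeakSet,
              gates: GateConfig | None = None,
              peaks_cfg: PeakConfig | None = None,
              max_lag_frames: int | None = None,
              keep_r_by_lag: bool = False) -> list[PairStat]:
    """PairStat for every unordered pair of active cells, gated.

    The lag grid defaults to ceil(frame_rate × d_max / v_min) frames — the
    largest delay any gate-passing pair can have — so no admissible edge is
    missed for lack of lag range.  Pairs involving inactive cells are skipped
    (their correlations are never computed).
    """
    gates = gates or GateConfig()
    peaks_cfg = peaks_cfg or PeakConfig()
    if max_lag_frames is None:
        max_lag_frames = int(math.ceil(dff.frame_rate
                                       * gates.resolved_max_lag_s()))
    max_lag_frames = min(max_lag_frames, dff.n_frames - 3)

    ids = dff.cell_ids
    roit = rois.set_index("cell_id")
    missing = [c for c in ids if c not in roit.index]
    if missing:
        raise ValueError(f"cells missing from ROI table: {missing[:5]}")
    xy = roit.loc[ids, ["x", "y"]].to_numpy(dtype=float)

    active_idx = [k for k in range(len(ids))
                  if peaks.is_active[k] and dff.valid[k]]
    n_skipped = len(ids) - len(active_idx)
    if n_skipped:
        logger.debug("skipping %d inactive/invalid cells", n_skipped)
    if len(active_idx) < 2:
        logger.warning("fewer than 2 active cells; no pairs computed")
        return []

    engine = LagEngine(dff.dff, max_lag_frames, dff.frame_rate)
    counts = peaks.counts_by_id()
    out: list[PairStat] = []
    for i, j in combinations(active_idx, 2):
        a, b = sorted((ids[i], ids[j]))
        if a != ids[i]:
            i, j = j, i
        d = float(np.hypot(*(xy[i] - xy[j])))
        lc = engine.correlate(i, j)
        speed = propagation_speed(d, lc.best_lag_s)
        p = PairStat(cell_a=ids[i], cell_b=ids[j], distance_um=d,
                     r_max=lc.r_max, best_lag_s=lc.best_lag_s,
                     speed_um_s=speed,
                     r_by_lag=lc.r if keep_r_by_lag else None,
                     lags_s=(lc.lags / dff.frame_rate) if keep_r_by_lag
                     else None)
        p = pair_filter(p, counts, gates, peaks_cfg)
        if p.verdict == "excluded":
            logger.debug("pair (%s, %s) excluded: %s", p.cell_a, p.cell_b,
                         p.reason)
        out.append(p)
    return out


def pair_frame(pairs: list[PairStat]) -> pd.DataFrame:
    """Tabular export of pair statistics."""
    return pd.DataFrame(
        [{"cell_a": p.cell_a, "cell_b": p.cell_b,
          "distance_um": p.distance_um, "r_max": p.r_max,
          "best_lag_s": p.best_lag_s if p.best_lag_s is not None else np.nan,
          "speed_um_s": p.speed_um_s, "verdict": p.verdict,
          "reason": p.reason}
         for p in pairs],
        columns=["cell_a", "cell_b", "distance_um", "r_max", "best_lag_s",
                 "speed_um_s", "verdict", "reason"])
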