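"""Synthetic calcium recordings with known connectivity ground truth.

The generator emulates the recording geometry the analysis is designed for:
a 10-min, 40-Hz recording of tens to hundreds of cells scattered in a 2-D
field, where a subpopulation of autonomously rhythmic "source" cells drives
calcium events that propagate to coupled neighbours at speeds inside the
physiological 4–25 μm/s window.  Fluorescence is rendered with a fast
GCaMP-like difference-of-exponentials transient kernel on a baseline, plus
additive Gaussian noise.  Every draw flows from a single integer seed via
``numpy.random.SeedSequence`` spawning (layout / truth / render streams), so
a dataset is a pure function of its SimConfig.

The coupling graph is a star forest: each edge joins a source to a
previously uncoupled non-source cell.  Receiver–receiver chains or shared
paths would themselves be genuinely co-active, which would make the edge
list ill-defined as a recovery target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import TraceMatrix

logger = logging.getLogger("gliowave.synthetic")

__all__ = ["SimConfig", "GroundTruth", "generate_layout", "generate_truth",
           "render_fluorescence", "write_dataset", "ablate_sources",
           "simulate_field"]


@dataclass
class SimConfig:
    """Study conditions for one simulated field.

    Defaults mirror the modelled experiments: 10-min recordings at 40 Hz,
    a 400-μm field, rhythmic sources with ~20-s periods, couplings confined
    to ≤ 100 μm with speeds well inside [4, 25] μm/s, ΔF/F transient
    amplitude 1.0 against noise σ = 0.1, and a sparse Poisson background so
    genuinely inactive (< 4 peaks / 10 min) cells occur.
    """

    n_cells: int = 50
    field_um: float = 400.0
    frame_rate: float = 40.0
    duration_s: float = 600.0
    n_sources: int = 10
    source_period_s: float = 20.0
    source_jitter: float = 0.05         # per-event sd, fraction of period
    period_spread: float = 0.15         # per-source period spread (± fraction)
    n_edges: int = 10
    speed_range_um_s: tuple[float, float] = (6.0, 20.0)
    edge_fidelity: float = 0.9
    edge_d_min_um: float = 20.0         # couplings span at least this distance
    edge_d_max_um: float = 100.0
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.5
    kernel_amplitude: float = 1.0       # ΔF/F units
    noise_sigma: float = 0.1            # ΔF/F units
    baseline_f0: float = 100.0
    background_rate_per_min: float = 0.2
    bleach_frac: float = 0.0            # optional linear bleach over the run
    min_separation_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least 1 cell")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= 0:
            raise ValueError("kernel times must be positive")
        if self.kernel_decay_s <= self.kernel_rise_s:
            raise ValueError("kernel decay must exceed rise")
        lo, hi = self.speed_range_um_s
        if not 0 < lo <= hi:
            raise ValueError("invalid speed range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speed_range_um_s"] = list(self.speed_range_um_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "speed_range_um_s" in d:
            d["speed_range_um_s"] = tuple(d["speed_range_um_s"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Simulator ground truth used to score edge recovery."""

    true_edges: pd.DataFrame    # cell_a, cell_b, distance_um, speed_um_s, delay_s
    source_cells: list[str]
    source_times: dict[str, np.ndarray]       # autonomous events of sources
    propagated_times: dict[str, np.ndarray]   # events received along edges
    background_times: dict[str, np.ndarray]   # independent Poisson events
    noiseless_dff: np.ndarray | None = None   # filled by render_fluorescence
    cell_ids: list[str] = field(default_factory=list)

    def event_times(self, cid: str) -> np.ndarray:
        """All events of one cell, sorted."""
        parts = [d.get(cid, np.empty(0)) for d in
                 (self.source_times, self.propagated_times,
                  self.background_times)]
        return np.sort(np.concatenate(parts))

    def all_event_times(self) -> dict[str, np.ndarray]:
        return {cid: self.event_times(cid) for cid in self.cell_ids}

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b)))
                for a, b in zip(self.true_edges["cell_a"],
                                self.true_edges["cell_b"])}


def _cell_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"c{i:0{width}d}" for i in range(n)]


def generate_layout(cfg: SimConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Uniform random centroids with a minimum pairwise separation.

    Sequential rejection sampling; raises if the field cannot accommodate
    ``n_cells`` at the separation within a bounded number of attempts.
    """
    if cfg.n_cells < 2:
        raise ValueError("a layout needs at least 2 cells")
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(3)[0])
    pts: list[np.ndarray] = []
    max_attempts = 1000 * cfg.n_cells
    attempts = 0
    while len(pts) < cfg.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_cells} cells at "
                f"{cfg.min_separation_um} μm separation in a "
                f"{cfg.field_um} μm field")
        attempts += 1
        p = rng.uniform(0.0, cfg.field_um, size=2)
        if all(np.hypot(*(p - q)) >= cfg.min_separation_um for q in pts):
            pts.append(p)
    xy = np.vstack(pts)
    return pd.DataFrame({"cell_id": _cell_ids(cfg.n_cells),
                         "x": xy[:, 0], "y": xy[:, 1]})


def _source_train(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """One rhythmic event train: per-source period, phase, per-event jitter."""
    period = cfg.source_period_s * rng.uniform(1.0 - cfg.period_spread,
                                               1.0 + cfg.period_spread)
    t = rng.uniform(0.0, period)
    times = []
    while t < cfg.duration_s:
        times.append(t)
        step = period * (1.0 + cfg.source_jitter * rng.standard_normal())
        t += max(step, 0.2 * period)
    return np.asarray(times)


def generate_truth(rois: pd.DataFrame, cfg: SimConfig,
                   rng: np.random.Generator | None = None) -> GroundTruth:
    """Sources, coupling graph, propagation delays and event trains.

    Each of ``n_edges`` couplings joins a source to a distinct, previously
    uncoupled non-source cell at a distance in [edge_d_min, edge_d_max], and
    carries a speed drawn from ``speed_range_um_s`` (delay = distance /
    speed).  Source events cross an edge independently with probability
    ``edge_fidelity``.  Cells that are neither sources nor receivers fire
    independent Poisson background events.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(3)[1])
    ids = list(rois["cell_id"])
    xy = rois[["x", "y"]].to_numpy(dtype=float)
    n = len(ids)
    if cfg.n_sources > n:
        raise ValueError("more sources than cells")

    src_idx = sorted(rng.choice(n, size=cfg.n_sources, replace=False).tolist())
    sources = [ids[i] for i in src_idx]

    # couplings: round-robin over sources, partners uncoupled non-sources
    coupled: set[int] = set()
    edges: list[dict] = []
    if cfg.n_edges > 0 and cfg.n_sources == 0:
        raise ValueError("edges require at least one source")
    order = list(src_idx)
    attempts = 0
    while len(edges) < cfg.n_edges:
        if attempts > 100 * max(cfg.n_edges, 1):
            raise ValueError(
                f"could only place {len(edges)} of {cfg.n_edges} couplings "
                "within the distance window")
        attempts += 1
        s = order[len(edges) % len(order)]
        d_all = np.hypot(*(xy - xy[s]).T)
        elig = [k for k in range(n)
                if k != s and k not in src_idx and k not in coupled
                and cfg.edge_d_min_um <= d_all[k] <= cfg.edge_d_max_um]
        if not elig:
            order = order[1:] + order[:1]   # try another source
            if all(not _eligible(xy, s2, src_idx, coupled, cfg)
                   for s2 in src_idx):
                raise ValueError(
                    f"could only place {len(edges)} of {cfg.n_edges} "
                    "couplings within the distance window")
            continue
        k = int(rng.choice(elig))
        coupled.add(k)
        d = float(d_all[k])
        v = float(rng.uniform(*cfg.speed_range_um_s))
        a, b = sorted((ids[s], ids[k]))
        edges.append({"cell_a": a, "cell_b": b, "source": ids[s],
                      "receiver": ids[k], "distance_um": d, "speed_um_s": v,
                      "delay_s": d / v})

    source_times = {ids[i]: _source_train(rng, cfg) for i in src_idx}

    propagated: dict[str, list[np.ndarray]] = {}
    for e in edges:
        src_t = source_times[e["source"]]
        keep = rng.random(src_t.size) < cfg.edge_fidelity
        arr = src_t[keep] + e["delay_s"]
        arr = arr[arr < cfg.duration_s]
        propagated.setdefault(e["receiver"], []).append(arr)
    propagated_times = {cid: np.sort(np.concatenate(v))
                        for cid, v in propagated.items()}

    background_times: dict[str, np.ndarray] = {}
    involved = set(src_idx) | coupled
    rate_s = cfg.background_rate_per_min / 60.0
    for k in range(n):
        if k in involved:
            continue
        n_ev = rng.poisson(rate_s * cfg.duration_s)
        background_times[ids[k]] = np.sort(
            rng.uniform(0.0, cfg.duration_s, size=n_ev))

    cols = ["cell_a", "cell_b", "source", "receiver", "distance_um",
            "speed_um_s", "delay_s"]
    return GroundTruth(true_edges=pd.DataFrame(edges, columns=cols),
                       source_cells=sources, source_times=source_times,
                       propagated_times=propagated_times,
                       background_times=background_times, cell_ids=ids)


def _eligible(xy, s, src_idx, coupled, cfg) -> bool:
    d_all = np.hypot(*(xy - xy[s]).T)
    return any(k != s and k not in src_idx and k not in coupled
               and cfg.edge_d_min_um <= d_all[k] <= cfg.edge_d_max_um
               for k in range(len(xy)))


def ablate_sources(truth: GroundTruth) -> GroundTruth:
    """Remove the rhythmic sources' drive: their autonomous events and every
    propagated event disappear; background events are untouched.

    Computational analogue of eliminating the rhythmic-hub subpopulation.
    """
    return GroundTruth(true_edges=truth.true_edges.iloc[0:0].copy(),
                       source_cells=list(truth.source_cells),
                       source_times={}, propagated_times={},
                       background_times=dict(truth.background_times),
                       cell_ids=list(truth.cell_ids))


def _kernel(dt: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalised to amplitude."""
    rise, decay = cfg.kernel_rise_s, cfg.kernel_decay_s
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    h = np.zeros_like(dt)
    pos = dt >= 0
    h[pos] = (np.exp(-dt[pos] / decay) - np.exp(-dt[pos] / rise)) / peak
    return cfg.kernel_amplitude * h


def render_fluorescence(truth: GroundTruth, cfg: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> TraceMatrix:
    """Render raw fluorescence from the event trains.

    Noiseless ΔF/F is the sum of transient kernels over each cell's events
    (evaluated at exact sub-frame offsets); raw F = baseline_f0 × (1 + ΔF/F)
    plus Gaussian noise of sd noise_sigma × baseline_f0.  The noiseless ΔF/F
    is retained on the GroundTruth for oracle comparisons.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(3)[2])
    n_frames = int(round(cfg.duration_s * cfg.frame_rate))
    n = len(truth.cell_ids)
    dff = np.zeros((n_frames, n))
    support = int(np.ceil((7.0 * cfg.kernel_decay_s) * cfg.frame_rate))
    for j, cid in enumerate(truth.cell_ids):
        for t_ev in truth.event_times(cid):
            i0 = int(np.floor(t_ev * cfg.frame_rate))
            i1 = min(i0 + support, n_frames)
            if i0 >= n_frames:
                continue
            idx = np.arange(max(i0, 0), i1)
            dff[idx, j] += _kernel(idx / cfg.frame_rate - t_ev, cfg)
    truth.noiseless_dff = dff.copy()

    baseline = cfg.baseline_f0
    raw = baseline * (1.0 + dff)
    if cfg.bleach_frac:
        fade = 1.0 - cfg.bleach_frac * np.arange(n_frames) / n_frames
        raw = raw * fade[:, None]
    raw = raw + rng.normal(0.0, cfg.noise_sigma * baseline, size=raw.shape)
    return TraceMatrix(values=raw, frame_rate=cfg.frame_rate,
                       cell_ids=list(truth.cell_ids))


def simulate_field(cfg: SimConfig, ablated: bool = False
                   ) -> tuple[pd.DataFrame, GroundTruth, TraceMatrix]:
    """Layout → truth → render, all seeded from ``cfg.seed``.

    With ``ablated=True`` the same field is rendered with the rhythmic
    sources' drive removed (identical layout, background and noise streams),
    giving a paired intact/ablated contrast.
    """
    seqs = np.random.SeedSequence(cfg.seed).spawn(3)
    rois = generate_layout(cfg, np.random.default_rng(seqs[0]))
    truth = generate_truth(rois, cfg, np.random.default_rng(seqs[1]))
    if ablated:
        truth = ablate_sources(truth)
    traces = render_fluorescence(truth, cfg, np.random.default_rng(seqs[2]))
    return rois, truth, traces


def write_dataset(rois: pd.DataFrame, traces: TraceMatrix,
                  truth: GroundTruth, out_dir: str | Path,
                  cfg: SimConfig) -> dict[str, Path]:
    """Write the plain-text dataset: traces, ROIs, truth edges, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"traces": out / "traces.csv", "rois": out / "rois.csv",
             "truth_edges": out / "truth_edges.csv",
             "manifest": out / "manifest.json"}
    df = pd.DataFrame(traces.values, columns=traces.cell_ids)
    df.insert(0, "time_s", traces.times_s)
    df.to_csv(paths["traces"], index=False)
    rois.to_csv(paths["rois"], index=False)
    truth.true_edges.to_csv(paths["truth_edges"], index=False)
    manifest = {"config": cfg.to_dict(), "seed": cfg.seed,
                "n_cells": len(traces.cell_ids),
                "n_frames": traces.n_frames,
                "source_cells": truth.source_cells}
    paths["manifest"].write_text(json.dumps(manifest, indent=2,
                                            sort_keys=True))
    logger.info("dataset written to %s", out)
    return paths
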