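"""End-to-end orchestration: traces → co-activity → null → network → report.

``run_analyze`` executes the full procedure on a trace/ROI pair (or a
simulated field), writes every intermediate table as plain CSV/JSON, and
returns a report whose counts are internally consistent.  With a
ground-truth edge list the report also scores edge recovery
(precision/recall/F1).  Identical config + seed reproduce every output byte
(the report's timestamp field aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .coactivity import all_pairs, pair_frame
from .io import load_roi_csv, load_traces_csv
from .network import (build_network, classify_periodic, edge_frame,
                      node_frame, summarize)
from .nullmodel import build_null
from .synthetic import GroundTruth, SimConfig, simulate_field, write_dataset
from .traces import TraceMatrix, compute_dff, detect_peaks, event_rate

logger = logging.getLogger("gliowave.pipeline")

__all__ = ["RunConfig", "run_analyze", "run_compare", "score_edges",
           "analyze_field"]

#: report keys that compare_a/b treat as gate parameters
_GATE_KEYS = ("gates", "peaks", "null", "network", "baseline")


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    traces_csv: str | None = None
    roi_csv: str | None = None
    truth_edges_csv: str | None = None
    sim: SimConfig | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = {"analysis": self.analysis.to_dict(),
                   "sim": self.sim.to_dict() if self.sim else None,
                   "seed": self.seed}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def score_edges(predicted: set[tuple[str, str]],
                truth: set[tuple[str, str]]) -> dict:
    """Precision/recall/F1 of an undirected edge set against ground truth."""
    predicted = {tuple(sorted(e)) for e in predicted}
    truth = {tuple(sorted(e)) for e in truth}
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
            "recall": recall, "f1": f1}


def analyze_field(traces: TraceMatrix, rois: pd.DataFrame,
                  cfg: AnalysisConfig, seed: int | None = None) -> dict:
    """Run every analysis stage in memory; returns all stage products.

    The null-model seed is split from the run seed with SeedSequence so the
    surrogate draws are independent of any simulation stream.
    """
    seed = cfg.seed if seed is None else seed
    null_seed = int(np.random.SeedSequence(seed).spawn(5)[4]
                    .generate_state(1)[0] % (2 ** 31))

    dff = compute_dff(traces, cfg.baseline)
    peaks = detect_peaks(dff, cfg.peaks)
    pairs = all_pairs(dff, rois, peaks, cfg.gates, cfg.peaks)
    passing = [p for p in pairs if p.verdict == "pass"]
    if passing:
        null = build_null(dff, pairs, cfg.null, cfg.gates, seed=null_seed)
        r0 = null.threshold_r0
    else:
        logger.warning("no gate-passing pairs; threshold undefined, "
                       "network will be edgeless")
        null, r0 = None, float("nan")
    net = build_network(pairs, r0, rois, peaks)
    periodic = classify_periodic(peaks, cfg.network)
    summary = summarize(net, periodic)
    summary["event_rate_per_min_per_100"] = event_rate(
        peaks, traces.duration_s, traces.n_cells)
    return {"dff": dff, "peaks": peaks, "pairs": pairs, "null": null,
            "r0": r0, "network": net, "periodic": periodic,
            "summary": summary}


def run_analyze(cfg: RunConfig) -> dict:
    """Full pipeline with artifact files; returns the run report.

    Input is either a traces/ROI CSV pair or a simulation config (which is
    then generated in place and written alongside the analysis outputs).
    """
    t_start = time.time()
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        rois, truth, traces = simulate_field(sim)
        truth_edges = truth.edge_set()
        if cfg.out_dir:
            write_dataset(rois, traces, truth, Path(cfg.out_dir) / "data", sim)
    elif cfg.traces_csv and cfg.roi_csv:
        traces = load_traces_csv(cfg.traces_csv,
                                 cfg.analysis.frame_rate_hz)
        rois = load_roi_csv(cfg.roi_csv)
        missing = set(traces.cell_ids) - set(rois["cell_id"])
        if missing:
            raise ValueError(
                f"cell id(s) in traces but not in ROI table: "
                f"{sorted(missing)[:5]}")
        truth_edges = None
        if cfg.truth_edges_csv:
            te = pd.read_csv(cfg.truth_edges_csv,
                             dtype={"cell_a": str, "cell_b": str})
            truth_edges = {tuple(sorted((a, b)))
                           for a, b in zip(te["cell_a"], te["cell_b"])}
    else:
        raise ValueError("RunConfig needs traces_csv+roi_csv or a sim config")

    res = analyze_field(traces, rois, cfg.analysis, seed=cfg.seed)
    pairs, peaks, net = res["pairs"], res["peaks"], res["network"]

    n_excluded = {}
    for p in pairs:
        if p.verdict == "excluded":
            n_excluded[p.reason] = n_excluded.get(p.reason, 0) + 1
    report = {
        "provenance": {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                       "gliowave_version": __version__},
        "analysis_config": cfg.analysis.to_dict(),
        "counts": {
            "n_cells": traces.n_cells,
            "n_active": int(peaks.is_active.sum()),
            "n_pairs_computed": len(pairs),
            "n_pairs_excluded": n_excluded,
            "n_pairs_passing": sum(1 for p in pairs if p.verdict == "pass"),
            "n_edges": net.number_of_edges(),
        },
        "threshold_r0": res["r0"],
        "null": res["null"].summary() if res["null"] else None,
        "summary": res["summary"],
    }
    if truth_edges is not None:
        pred = {tuple(sorted(e)) for e in net.edges()}
        report["truth_scoring"] = score_edges(pred, truth_edges)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        peaks.to_frame().to_csv(out / "peaks.csv", index=False)
        peaks.activity_frame().to_csv(out / "activity.csv", index=False)
        pair_frame(pairs).to_csv(out / "pairs.csv", index=False)
        edge_frame(net).to_csv(out / "edges.csv", index=False)
        node_frame(net, res["periodic"]).to_csv(out / "nodes.csv",
                                                index=False)
        if res["null"] is not None:
            (out / "null.json").write_text(
                json.dumps(res["null"].summary(), indent=2, sort_keys=True))
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        # wall-clock facts live apart so report.json is seed-deterministic
        (out / "run_meta.json").write_text(json.dumps(
            {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
             "runtime_s": round(time.time() - t_start, 3)}, indent=2))
    logger.info("analysis complete: %d active cells, %d edges, r0=%s",
                report["counts"]["n_active"], report["counts"]["n_edges"],
                f"{res['r0']:.3f}" if res["r0"] == res["r0"] else "nan")
    return report


def run_compare(report_a: dict, report_b: dict) -> dict:
    """Side-by-side contrast of two runs (e.g. control vs knockdown model).

    Reports deltas (b − a) of the quantities contrasted between intact and
    perturbed networks: communicating-cell percentage, hub and periodic-cell
    counts, and the population event rate.  A mismatch in analysis
    parameters is recorded as a warning, not an error.
    """
    warnings = []
    ca = report_a.get("analysis_config", {})
    cb = report_b.get("analysis_config", {})
    for key in _GATE_KEYS:
        if ca.get(key) != cb.get(key):
            warnings.append(f"analysis parameter block {key!r} differs "
                            "between runs")
    sa, sb = report_a["summary"], report_b["summary"]

    def delta(key):
        return sb.get(key, 0) - sa.get(key, 0)

    return {
        "communicating_pct": {"a": sa.get("communicating_pct"),
                              "b": sb.get("communicating_pct"),
                              "delta": delta("communicating_pct")},
        "n_hubs": {"a": sa.get("n_hubs"), "b": sb.get("n_hubs"),
                   "delta": delta("n_hubs")},
        "n_periodic": {"a": sa.get("n_periodic"), "b": sb.get("n_periodic"),
                       "delta": delta("n_periodic")},
        "event_rate_per_min_per_100": {
            "a": sa.get("event_rate_per_min_per_100"),
            "b": sb.get("event_rate_per_min_per_100"),
            "delta": delta("event_rate_per_min_per_100")},
        "warnings": warnings,
    }
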