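"""Co-activity graph construction and the count-based summary metrics.

Nodes are active cells (isolates included); an undirected edge joins a
gate-passing pair whose connectivity strength reaches the surrogate
threshold r0.  Summaries follow the conventions used for glioma
calcium-imaging networks: "communicating cells" are nodes with degree ≥ 1,
hubs are the top 5% of the degree distribution, and "periodic cells" carry
an autonomously rhythmic event train (operationalised by a low coefficient
of variation of inter-peak intervals).
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

from .config import NetworkConfig
from .coactivity import PairStat
from .traces import PeakSet

logger = logging.getLogger("gliowave.network")

__all__ = ["build_network", "communicating_fraction", "find_hubs",
           "classify_periodic", "summarize", "node_frame", "edge_frame"]


def build_network(pairs: list[PairStat], r0: float, rois: pd.DataFrame,
                  peaks: PeakSet) -> nx.Graph:
    """Undirected simple graph: nodes = active cells, edges = significant pairs.

    An edge exists iff the pair passed every physiological gate and its
    r_max ≥ r0.  A NaN threshold (no usable null) yields an edgeless graph.
    """
    g = nx.Graph()
    roit = rois.set_index("cell_id")
    counts = peaks.counts_by_id()
    for cid, active in zip(peaks.cell_ids, peaks.is_active):
        if active:
            g.add_node(cid, x=float(roit.loc[cid, "x"]),
                       y=float(roit.loc[cid, "y"]),
                       n_peaks=int(counts[cid]))
    if not (isinstance(r0, float) and math.isnan(r0)):
        for p in pairs:
            if p.verdict == "pass" and p.r_max >= r0:
                g.add_edge(p.cell_a, p.cell_b, r_max=p.r_max,
                           best_lag_s=p.best_lag_s, speed_um_s=p.speed_um_s)
    g.graph["r0"] = r0
    return g


def communicating_fraction(net: nx.Graph) -> float:
    """Percentage of active cells with at least one significant edge."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("network has no nodes")
    communicating = sum(1 for _, d in net.degree() if d >= 1)
    return 100.0 * communicating / n


def find_hubs(net: nx.Graph, top_frac: float = 0.05) -> dict[str, bool]:
    """Flag nodes in the top ``top_frac`` of the degree distribution.

    The cutoff is the (1 − top_frac) linear-interpolation percentile of the
    degree sequence; every node tied at the cutoff is included, but isolates
    are never hubs.  Flags are also written to the node attribute
    ``is_hub``.
    """
    degrees = dict(net.degree())
    if not degrees:
        return {}
    seq = np.array(list(degrees.values()), dtype=float)
    cutoff = np.percentile(seq, 100.0 * (1.0 - top_frac))
    hubs = {cid: bool(d >= cutoff and d >= 1) for cid, d in degrees.items()}
    nx.set_node_attributes(net, hubs, "is_hub")
    return hubs


def classify_periodic(peaks: PeakSet,
                      cfg: NetworkConfig | None = None) -> dict[str, bool]:
    """Rhythmicity flags from the inter-peak-interval coefficient of variation.

    A cell is periodic iff it has at least ``periodic_min_peaks`` peaks and
    CV(inter-peak intervals) ≤ ``periodic_cv_max``.  Cells with fewer than
    two peaks have no defined CV and are never periodic.
    """
    cfg = cfg or NetworkConfig()
    out: dict[str, bool] = {}
    for cid, times in zip(peaks.cell_ids, peaks.peak_times):
        if len(times) < max(cfg.periodic_min_peaks, 2):
            out[cid] = False
            continue
        ipi = np.diff(times)
        mean = ipi.mean()
        if mean <= 0:
            out[cid] = False
            continue
        cv = ipi.std(ddof=0) / mean
        out[cid] = bool(cv <= cfg.periodic_cv_max)
    return out


def summarize(net: nx.Graph, periodic: dict[str, bool] | None = None) -> dict:
    """Count-based network summary.

    Edge means are taken over the edge attributes; an empty graph reports
    zeros (except the node count).  ``mean_edge_speed`` averages only edges
    with a defined speed.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    periodic = periodic or {}
    n_periodic = sum(1 for cid in net.nodes if periodic.get(cid, False))
    if n == 0:
        return {"n_active": 0, "n_edges": 0, "communicating_pct": 0.0,
                "n_hubs": 0, "n_periodic": 0, "mean_degree": 0.0,
                "mean_edge_r": 0.0, "mean_edge_speed": 0.0}
    hubs = find_hubs(net) if e else {}
    r_vals = [d["r_max"] for _, _, d in net.edges(data=True)]
    s_vals = [d["speed_um_s"] for _, _, d in net.edges(data=True)
              if d.get("speed_um_s") is not None
              and not math.isnan(d["speed_um_s"])]
    return {
        "n_active": n,
        "n_edges": e,
        "communicating_pct": communicating_fraction(net),
        "n_hubs": sum(hubs.values()),
        "n_periodic": n_periodic,
        "mean_degree": 2.0 * e / n,
        "mean_edge_r": float(np.mean(r_vals)) if r_vals else 0.0,
        "mean_edge_speed": float(np.mean(s_vals)) if s_vals else 0.0,
    }


def node_frame(net: nx.Graph, periodic: dict[str, bool] | None = None
               ) -> pd.DataFrame:
    """Node table: `cell_id, x, y, degree, is_hub, is_periodic, n_peaks`."""
    periodic = periodic or {}
    hubs = find_hubs(net)
    rows = [{"cell_id": cid, "x": d.get("x"), "y": d.get("y"),
             "degree": net.degree(cid), "is_hub": hubs.get(cid, False),
             "is_periodic": periodic.get(cid, False),
             "n_peaks": d.get("n_peaks")}
            for cid, d in sorted(net.nodes(data=True))]
    return pd.DataFrame(rows, columns=["cell_id", "x", "y", "degree",
                                       "is_hub", "is_periodic", "n_peaks"])


def edge_frame(net: nx.Graph) -> pd.DataFrame:
    """Edge table: `cell_a, cell_b, r_max, best_lag_s, speed_um_s`."""
    rows = [{"cell_a": min(a, b), "cell_b": max(a, b), "r_max": d["r_max"],
             "best_lag_s": d["best_lag_s"], "speed_um_s": d["speed_um_s"]}
            for a, b, d in net.edges(data=True)]
    rows.sort(key=lambda r: (r["cell_a"], r["cell_b"]))
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "r_max",
                                       "best_lag_s", "speed_um_s"])
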