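"""Screen scoring and small morphometric statistics.

The triple-readout knockdown screen scores each well against its plate's
negative controls: z = (X − μ)/s.d., with μ the mean of the negative-control
wells and s.d. the standard deviation of the whole plate population for that
readout (sample, n−1 convention).  The three readouts — nascent-protein
puncta, ATP intensity and tumour-microtube (TM) length — are aggregated per
condition and ranked so that the strongest loss-of-function scores first.

Also here: the TM morphometric gate (length > 10 μm, calibre 0.5–2.5 μm)
and the EdU proliferation index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["robust_z", "rank_hits", "classify_protrusion", "edu_index",
           "make_synthetic_screen", "DegeneratePlateError", "READOUTS"]

READOUTS = ("nascent_protein_puncta", "atp_intensity", "tm_length")


class DegeneratePlateError(ValueError):
    """Raised when a plate/readout has zero population variance."""


def robust_z(plate: pd.DataFrame, formula: str = "paper") -> pd.DataFrame:
    """Per-well z-scores within each (plate, readout) group.

    ``formula="paper"``: z = (X − mean of negative controls) / sd of all
    wells on the plate (ddof=1).  ``formula="mad"``: a true robust variant,
    z = (X − median of negative controls) / (1.4826 × MAD of all wells).
    Returns the input with a ``z`` column appended.
    """
    if formula not in ("paper", "mad"):
        raise ValueError(f"unknown formula {formula!r}")
    out = []
    for (plate_id, readout), grp in plate.groupby(["plate_id", "readout"],
                                                  sort=True):
        neg = grp.loc[grp["is_negative_control"], "value"]
        if len(neg) < 2:
            raise ValueError(
                f"plate {plate_id!r} readout {readout!r}: needs >= 2 "
                "negative-control wells")
        values = grp["value"].to_numpy(dtype=float)
        if formula == "paper":
            mu = float(neg.mean())
            sd = float(np.std(values, ddof=1))
        else:
            mu = float(neg.median())
            sd = float(1.4826 * np.median(np.abs(values - np.median(values))))
        if sd == 0:
            raise DegeneratePlateError(
                f"plate {plate_id!r} readout {readout!r}: zero population "
                "spread")
        g = grp.copy()
        g["z"] = (values - mu) / sd
        out.append(g)
    return pd.concat(out, ignore_index=True)


def rank_hits(z_table: pd.DataFrame, agg: str = "mean",
              sign: dict[str, float] | None = None) -> pd.DataFrame:
    """Aggregate per-condition z across readouts and rank loss-of-function.

    All three readouts decrease under loss of function, so their z-scores
    are already sign-aligned (negative = stronger hit); ``sign`` can flip
    individual readouts if a custom readout scores inversely.  Conditions
    are ranked ascending on the aggregate (default: mean of available
    readouts; ``agg`` may also be "min" or "max"), ties broken
    lexicographically by condition name.  Conditions missing a readout are
    aggregated over the remaining ones and flagged (``n_readouts``).
    """
    if agg not in ("mean", "min", "max"):
        raise ValueError(f"unknown aggregation {agg!r}")
    sign = sign or {}
    t = z_table.copy()
    t["z_signed"] = [z * sign.get(r, 1.0)
                     for z, r in zip(t["z"], t["readout"])]
    rows = []
    for cond, grp in t[~t["is_negative_control"]].groupby("condition"):
        per_readout = grp.groupby("readout")["z_signed"].mean()
        agg_fn = {"mean": np.mean, "min": np.min, "max": np.max}[agg]
        rows.append({"condition": cond,
                     "z_aggregate": float(agg_fn(per_readout.to_numpy())),
                     "n_readouts": int(per_readout.size),
                     "complete": bool(per_readout.size == len(READOUTS))})
    ranked = pd.DataFrame(rows).sort_values(
        ["z_aggregate", "condition"], kind="mergesort").reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked


def classify_protrusion(length_um: float, calibre_um: float) -> bool:
    """TM morphometric gate: length strictly > 10 μm, calibre in [0.5, 2.5].

    Lengths of exactly 10 μm are excluded; the calibre bounds are inclusive.
    """
    if length_um <= 0 or calibre_um <= 0:
        raise ValueError("length and calibre must be positive")
    return length_um > 10.0 and 0.5 <= calibre_um <= 2.5


def edu_index(edu_pos: int, total_dapi: int) -> float:
    """Proliferation index: percentage of EdU⁺ cells among all (DAPI) cells."""
    if total_dapi <= 0:
        raise ValueError("total cell count must be positive")
    if not 0 <= edu_pos <= total_dapi:
        raise ValueError("EdU-positive count must be within [0, total]")
    return 100.0 * edu_pos / total_dapi


def make_synthetic_screen(n_conditions: int = 16, n_plates: int = 1,
                          hit_conditions: dict[str, float] | None = None,
                          n_neg_controls: int = 4, noise_sd: float = 1.0,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic screen plate table with planted hits.

    Each condition gets one well per readout per plate; readout values are
    baseline 100 plus Gaussian well noise.  ``hit_conditions`` maps a
    condition name to an effect in population-sd units applied to all three
    readouts (negative = loss of function).
    """
    rng = np.random.default_rng(seed)
    hit_conditions = hit_conditions or {}
    conditions = [f"gene{i:03d}" for i in range(n_conditions)]
    rows = []
    for p in range(n_plates):
        plate_id = f"P{p + 1}"
        for readout in READOUTS:
            for k in range(n_neg_controls):
                rows.append((plate_id, f"{readout[:2]}_neg{k}", "NEG_CTRL",
                             readout, 100.0 + noise_sd * rng.standard_normal(),
                             True))
            for cond in conditions:
                shift = hit_conditions.get(cond, 0.0) * noise_sd
                rows.append((plate_id, f"{readout[:2]}_{cond}", cond, readout,
                             100.0 + shift + noise_sd * rng.standard_normal(),
                             False))
    return pd.DataFrame(rows, columns=["plate_id", "well_id", "condition",
                                       "readout", "value",
                                       "is_negative_control"])
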