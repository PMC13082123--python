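"""Configuration objects for the co-activity pipeline.

Every physiological default mirrors the values used for the glioma
calcium-imaging networks this package models: distance gate 100 μm, propagation
speed window [4, 25] μm/s, activity gate ≥ 4 calcium peaks per 10-min
recording, surrogate percentile 95, minimum surrogate shift 300 s, hub
fraction 5%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class BaselineConfig:
    """How the basal fluorescence F0 is estimated per cell.

    method: "global-percentile" (one F0 per cell from the whole trace) or
    "rolling-percentile" (windowed, for drifting baselines).

    The percentile is taken on a boxcar-smoothed copy of the trace
    (``presmooth_s``, default 1 s): on an unsmoothed noisy trace a low
    percentile lands ~0.84 noise-sd below the true baseline, which inflates
    every ΔF/F amplitude by the same fraction.  Smoothing over a second
    (transients here last ~0.5 s but occupy a small duty cycle) suppresses
    that bias to the percent level.  Set to 0 to disable.
    """

    method: str = "global-percentile"
    q: float = 20.0
    window_s: float = 30.0
    presmooth_s: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("global-percentile", "rolling-percentile"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if not 0 < self.q < 100:
            raise ValueError("baseline percentile q must be in (0, 100)")


@dataclass
class PeakConfig:
    """Prominence-gated peak detection on ΔF/F.

    A local maximum counts as a calcium peak when its prominence is at least
    ``k`` times the robust per-cell noise scale (1.4826 × MAD of the first
    difference of ΔF/F, divided by √2).  ``min_separation_s`` is the
    refractory interval between accepted peaks.

    Candidate maxima are taken on a boxcar-smoothed copy of the trace
    (``smooth_s``, default 0.25 s): at tens of Hz the raw noise floor carries
    local maxima whose prominence exceeds a few noise scales hundreds of
    times per 10-min trace, which would void the ≥4-peak activity gate.  The
    noise scale itself is estimated on the unsmoothed trace, so the
    prominence threshold keeps its meaning; calcium transients are an order
    of magnitude slower than the window and pass nearly unattenuated.
    Windows at or below one frame disable smoothing.
    """

    k: float = 3.0
    min_separation_s: float = 1.0
    active_min_peaks: int = 4
    smooth_s: float = 0.25


@dataclass
class GateConfig:
    """Physiological pair-exclusion gates.

    Pairs farther apart than ``d_max_um`` are discarded; a pair's implied
    propagation speed (distance / |best lag|) must fall inside the closed
    window [v_min_um_s, v_max_um_s].  ``max_lag_s`` bounds the lag grid; when
    None it is derived as d_max / v_min (the largest physiologically
    admissible delay) so no gate-passing delay can be missed.
    """

    d_max_um: float = 100.0
    v_min_um_s: float = 4.0
    v_max_um_s: float = 25.0
    max_lag_s: float | None = None

    def resolved_max_lag_s(self) -> float:
        if self.max_lag_s is not None:
            return self.max_lag_s
        return self.d_max_um / self.v_min_um_s

    @classmethod
    def synchrony_1s(cls) -> "GateConfig":
        """Alternative edge rule: co-events within 100 μm and a 1-s timeframe.

        Disables the velocity window and restricts the lag grid to ±1 s.
        Kept as an explicit preset; not the default procedure.
        """
        return cls(d_max_um=100.0, v_min_um_s=0.0, v_max_um_s=float("inf"),
                   max_lag_s=1.0)


@dataclass
class NullConfig:
    """Linear-shift surrogate null model.

    One trace of each passing pair is circularly rotated by a random offset
    ΔT drawn uniformly from (dt_min_s, T); the lagged maximal correlation is
    recomputed on the same lag grid and pooled over pairs and draws.  The
    significance threshold r0 is the ``percentile``-th percentile of the pool
    (linear-interpolation definition).
    """

    n_surrogates_per_pair: int = 20
    percentile: float = 95.0
    dt_min_s: float = 300.0
    mode: str = "circular"          # or "truncate" (non-wrapping shift)
    pooling: str = "global"         # or "per_pair"

    def __post_init__(self) -> None:
        if self.mode not in ("circular", "truncate"):
            raise ValueError(f"unknown null mode {self.mode!r}")
        if self.pooling not in ("global", "per_pair"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


@dataclass
class NetworkConfig:
    """Graph summary parameters: hub quantile and periodicity rule."""

    hub_top_frac: float = 0.05
    periodic_min_peaks: int = 4
    periodic_cv_max: float = 0.3
    periodic_method: str = "cv"     # or "autocorr"


@dataclass
class AnalysisConfig:
    """Bundle of all stage parameters for one end-to-end analysis."""

    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    gates: GateConfig = field(default_factory=GateConfig)
    null: NullConfig = field(default_factory=NullConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    frame_rate_hz: float | None = None   # cross-checked against the trace CSV
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        # YAML reads the bare key `null:` as a None key; map it back
        d = {("null" if k is None else k): v for k, v in d.items()}
        kwargs: dict[str, Any] = {}
        for name, sub in (("baseline", BaselineConfig), ("peaks", PeakConfig),
                          ("gates", GateConfig), ("null", NullConfig),
                          ("network", NetworkConfig)):
            if name in d:
                kwargs[name] = sub(**d.pop(name))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
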