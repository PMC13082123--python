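"""Linear-shift surrogate null model and the pooled significance threshold."""

import numpy as np
import pytest

from gliowave import (build_null, compute_dff, detect_peaks, linear_shift,
                      significance_threshold, simulate_field)
from gliowave.coactivity import LagEngine, PairStat, all_pairs
from gliowave.config import GateConfig, NullConfig
from gliowave.nullmodel import NullModel
from gliowave.traces import DffTrace


def _null_from(values, seed=0):
    return NullModel(surrogate_r=np.asarray(values, dtype=float),
                     percentile=95.0, n_surrogates_per_pair=1, n_pairs=1,
                     seed=seed)


class TestLinearShift:
    def test_zero_shift_is_identity(self, rng):
        x = rng.standard_normal(50)
        assert np.array_equal(linear_shift(x, 0), x)

    def test_shift_by_n_rejected_and_rotation_group(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(ValueError):
            linear_shift(x, 50)
        assert np.array_equal(linear_shift(linear_shift(x, 49), 1), x)

    def test_values_are_a_permutation(self, rng):
        x = rng.standard_normal(101)
        s = linear_shift(x, 37)
        assert np.array_equal(np.sort(s), np.sort(x))
        assert s.mean() == pytest.approx(x.mean())
        assert s.var() == pytest.approx(x.var())

    def test_preserves_autocorrelation_structure(self, rng):
        # circular rotation leaves the circular autocovariance exactly intact
        x = np.convolve(rng.standard_normal(256), np.ones(8), "same")
        xc = x - x.mean()
        def circ_acov(z):
            f = np.fft.rfft(z)
            return np.fft.irfft(f * np.conj(f), len(z))
        assert np.allclose(circ_acov(xc),
                           circ_acov(np.roll(xc, 100)), atol=1e-8)


class TestSignificanceThreshold:
    def test_degenerate_distribution(self):
        assert significance_threshold(_null_from([0.1] * 100)) == pytest.approx(0.1)

    def test_matches_sort_and_index_oracle(self):
        vals = np.arange(100) / 100.0          # 0.00 .. 0.99
        got = significance_threshold(_null_from(vals))
        # brute linear-interpolation percentile: rank h = p/100 * (n-1)
        h = 0.95 * 99
        lo, frac = int(np.floor(h)), h - int(np.floor(h))
        s = np.sort(vals)
        expected = s[lo] + frac * (s[lo + 1] - s[lo])
        assert got == pytest.approx(expected, abs=1e-15)

    def test_nondecreasing_in_percentile(self, rng):
        null = _null_from(rng.uniform(-1, 1, 500))
        qs = [50, 75, 90, 95, 99]
        ts = [significance_threshold(null, q) for q in qs]
        assert all(a <= b for a, b in zip(ts, ts[1:]))

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(_null_from([]))

    def test_percentile_contract_on_pool(self, rng):
        null = _null_from(rng.uniform(0, 1, 2000))
        r0 = significance_threshold(null)
        frac_above = np.mean(null.surrogate_r >= r0)
        assert frac_above <= 0.05 + 1.0 / null.surrogate_r.size


class TestBuildNull:
    def _small(self, seed=0):
        from gliowave import SimConfig
        cfg = SimConfig(n_cells=12, field_um=200.0, frame_rate=20.0,
                        duration_s=180.0, n_sources=3, n_edges=3,
                        source_period_s=15.0, background_rate_per_min=0.5,
                        seed=seed)
        rois, truth, traces = simulate_field(cfg)
        dff = compute_dff(traces)
        peaks = detect_peaks(dff)
        pairs = all_pairs(dff, rois, peaks)
        return dff, pairs

    def test_seeded_reproducibility(self):
        dff, pairs = self._small()
        cfg = NullConfig(n_surrogates_per_pair=5, dt_min_s=60.0)
        a = build_null(dff, pairs, cfg, seed=42)
        b = build_null(dff, pairs, cfg, seed=42)
        assert np.array_equal(a.surrogate_r, b.surrogate_r)
        c = build_null(dff, pairs, cfg, seed=43)
        assert not np.array_equal(a.surrogate_r, c.surrogate_r)

    def test_pool_size_and_summary(self):
        dff, pairs = self._small()
        cfg = NullConfig(n_surrogates_per_pair=5, dt_min_s=60.0)
        null = build_null(dff, pairs, cfg, seed=1)
        n_pass = sum(1 for p in pairs if p.verdict == "pass")
        assert null.n_pairs == n_pass
        assert null.surrogate_r.size <= n_pass * 5
        s = null.summary()
        assert s["n_pooled"] == null.surrogate_r.size
        assert -1 <= s["threshold_r0"] <= 1

    def test_recording_too_short_rejected(self):
        dff, pairs = self._small()
        with pytest.raises(ValueError, match="too short"):
            build_null(dff, pairs, NullConfig(dt_min_s=1000.0), seed=0)

    def test_no_passing_pairs_rejected(self):
        dff, pairs = self._small()
        inactive = [PairStat(p.cell_a, p.cell_b, p.distance_um, p.r_max,
                             p.best_lag_s, p.speed_um_s, "excluded",
                             "distance") for p in pairs]
        with pytest.raises(ValueError, match="passing"):
            build_null(dff, inactive, NullConfig(dt_min_s=60.0), seed=0)

    def test_identical_traces_always_exceed_threshold(self, rng):
        # perfect coupling: observed r_max = 1 beats any non-degenerate null
        x = np.convolve(rng.standard_normal(2000), np.ones(10), "same")
        dff = DffTrace(dff=np.column_stack([x, x]), f0=np.ones(2),
                       frame_rate=20.0, cell_ids=["a", "b"])
        pairs = [PairStat("a", "b", 50.0, 1.0, 0.5, 10.0, "pass", "")]
        null = build_null(dff, pairs, NullConfig(dt_min_s=20.0), seed=0)
        assert 1.0 >= null.threshold_r0
        assert 1.0 >= np.max(null.surrogate_r)

    def test_relative_shift_leaves_lagged_r_nearly_unchanged(self, rng):
        """Rotating both traces together preserves their relative alignment;
        the per-lag r changes only through the wrapped overlap boundary."""
        x = np.convolve(rng.standard_normal(2000), np.ones(15), "same")
        y = 0.5 * x + np.convolve(rng.standard_normal(2000), np.ones(15),
                                  "same")
        base = LagEngine(np.column_stack([x, y]), 20, 20.0).r_by_lag(0, 1)
        s = 700
        rolled = LagEngine(np.column_stack([np.roll(x, s), np.roll(y, s)]),
                           20, 20.0).r_by_lag(0, 1)
        assert np.nanmax(np.abs(base - rolled)) < 0.05

    def test_white_noise_observed_below_threshold_most_of_the_time(self, rng):
        """Monte-Carlo self-consistency: independent pairs clear the 95th
        surrogate percentile about 5% of the time."""
        n, L = 600, 30
        hits = 0
        reps = 120
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            eng = LagEngine(np.column_stack([x, y]), L, 10.0)
            obs = eng.r_max(0, 1)
            dff = DffTrace(dff=np.column_stack([x, y]), f0=np.ones(2),
                           frame_rate=10.0, cell_ids=["a", "b"])
            pairs = [PairStat("a", "b", 50.0, obs, 1.0, 10.0, "pass", "")]
            null = build_null(dff, pairs,
                              NullConfig(n_surrogates_per_pair=40,
                                         dt_min_s=20.0),
                              seed=int(rng.integers(2**31)),
                              max_lag_frames=L)
            if obs >= null.threshold_r0:
                hits += 1
        # binomial 95% band around 0.05 at 120 reps, with margin
        assert hits / reps == pytest.approx(0.05, abs=0.06)

    def test_truncating_variant_also_calibrates(self, rng):
        dff, pairs = self._small()
        cfg = NullConfig(n_surrogates_per_pair=5, dt_min_s=60.0,
                         mode="truncate")
        null = build_null(dff, pairs, cfg, seed=3)
        assert np.isfinite(null.threshold_r0)
        assert -1 <= null.threshold_r0 <= 1
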