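"""Ground-truth calcium simulator: layout, coupling graph, rendering, I/O."""

import json

import numpy as np
import pandas as pd
import pytest

from gliowave import (SimConfig, ablate_sources, compute_dff, generate_layout,
                      generate_truth, render_fluorescence, simulate_field,
                      write_dataset)
from gliowave.io import load_traces_csv
from gliowave.synthetic import _kernel


class TestGenerateLayout:
    def test_minimum_pairwise_separation(self):
        cfg = SimConfig(n_cells=50, field_um=400.0, seed=2)
        rois = generate_layout(cfg)
        xy = rois[["x", "y"]].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        iu = np.triu_indices(len(xy), k=1)
        assert d[iu].min() >= cfg.min_separation_um
        assert (xy >= 0).all() and (xy <= cfg.field_um).all()

    def test_same_seed_same_layout(self):
        cfg = SimConfig(n_cells=20, seed=9)
        a, b = generate_layout(cfg), generate_layout(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(RuntimeError, match="could not place"):
            generate_layout(SimConfig(n_cells=200, field_um=30.0, seed=0))


class TestGenerateTruth:
    def _truth(self, **kw):
        cfg = SimConfig(seed=4, **kw)
        rois = generate_layout(cfg)
        return cfg, rois, generate_truth(rois, cfg)

    def test_delay_is_distance_over_speed(self):
        _, _, truth = self._truth()
        e = truth.true_edges
        assert np.allclose(e["delay_s"], e["distance_um"] / e["speed_um_s"])

    def test_edges_respect_distance_window(self):
        cfg, rois, truth = self._truth()
        assert (truth.true_edges["distance_um"] <= cfg.edge_d_max_um).all()
        assert (truth.true_edges["distance_um"] >= cfg.edge_d_min_um).all()

    def test_couplings_form_a_star_forest(self):
        _, _, truth = self._truth()
        receivers = list(truth.true_edges["receiver"])
        assert len(receivers) == len(set(receivers))
        assert not set(receivers) & set(truth.source_cells)

    def test_full_fidelity_propagates_every_fitting_event(self):
        cfg, rois, truth = self._truth(edge_fidelity=1.0)
        for _, e in truth.true_edges.iterrows():
            src = truth.source_times[e["source"]]
            expect = np.sort(src + e["delay_s"])
            expect = expect[expect < cfg.duration_s]
            got = truth.propagated_times[e["receiver"]]
            assert np.allclose(got, expect)

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError, match="couplings"):
            self._truth(n_cells=12, n_sources=2, n_edges=11)

    def test_ablation_removes_drive_keeps_background(self):
        _, _, truth = self._truth()
        ab = ablate_sources(truth)
        assert ab.true_edges.empty
        assert not ab.source_times and not ab.propagated_times
        for cid, t in truth.background_times.items():
            assert np.array_equal(ab.background_times[cid], t)


class TestRenderFluorescence:
    def test_no_events_no_noise_is_flat_baseline(self):
        cfg = SimConfig(n_cells=5, n_sources=0, n_edges=0,
                        background_rate_per_min=0.0, noise_sigma=0.0,
                        duration_s=30.0, seed=0)
        rois, truth, traces = simulate_field(cfg)
        assert np.allclose(traces.values, cfg.baseline_f0)
        assert np.allclose(truth.noiseless_dff, 0.0)

    def test_kernel_peak_amplitude_recovered_within_2pct(self):
        cfg = SimConfig(n_cells=2, n_sources=1, n_edges=0, noise_sigma=0.0,
                        source_period_s=30.0, duration_s=120.0,
                        background_rate_per_min=0.0, seed=1)
        rois, truth, traces = simulate_field(cfg)
        dff = compute_dff(traces)
        j = truth.cell_ids.index(truth.source_cells[0])
        est = dff.dff[:, j].max()
        assert est == pytest.approx(cfg.kernel_amplitude, rel=0.02)

    def test_kernel_rejects_bad_times(self):
        with pytest.raises(ValueError):
            SimConfig(kernel_rise_s=0.5, kernel_decay_s=0.1)

    def test_kernel_is_causal_and_peak_normalised(self):
        cfg = SimConfig()
        t = np.linspace(-1, 3.5, 2000)
        h = _kernel(t, cfg)
        assert np.all(h[t < 0] == 0)
        assert h.max() == pytest.approx(cfg.kernel_amplitude, rel=1e-3)

    def test_noise_scales_with_baseline(self):
        cfg = SimConfig(n_cells=3, n_sources=0, n_edges=0,
                        background_rate_per_min=0.0, noise_sigma=0.1,
                        duration_s=60.0, seed=5)
        _, _, traces = simulate_field(cfg)
        resid = traces.values - cfg.baseline_f0
        assert resid.std() == pytest.approx(cfg.noise_sigma * cfg.baseline_f0,
                                            rel=0.05)


class TestDeterminismAndIO:
    def test_dataset_is_pure_function_of_config(self, tmp_path):
        cfg = SimConfig(n_cells=10, n_sources=2, n_edges=2,
                        field_um=150.0, duration_s=20.0, seed=11)
        for d in ("a", "b"):
            rois, truth, traces = simulate_field(cfg)
            write_dataset(rois, traces, truth, tmp_path / d, cfg)
        for name in ("traces.csv", "rois.csv", "truth_edges.csv",
                     "manifest.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_round_trip_traces(self, tmp_path):
        cfg = SimConfig(n_cells=6, n_sources=2, n_edges=2,
                        field_um=120.0, duration_s=15.0, seed=3)
        rois, truth, traces = simulate_field(cfg)
        paths = write_dataset(rois, traces, truth, tmp_path, cfg)
        loaded = load_traces_csv(paths["traces"])
        assert loaded.cell_ids == traces.cell_ids
        assert loaded.frame_rate == pytest.approx(traces.frame_rate, rel=1e-6)
        assert np.allclose(loaded.values, traces.values, atol=1e-9)

    def test_manifest_embeds_config_and_seed(self, tmp_path):
        cfg = SimConfig(n_cells=6, n_sources=2, n_edges=2,
                        field_um=120.0, duration_s=15.0, seed=13)
        rois, truth, traces = simulate_field(cfg)
        paths = write_dataset(rois, traces, truth, tmp_path, cfg)
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == 13
        assert manifest["config"] == cfg.to_dict()
        te = pd.read_csv(paths["truth_edges"])
        assert (te["distance_um"] <= 100.0).all()


def test_injected_delays_recovered_to_frame_precision():
    """On a noiseless render the lagged-correlation peak sits within one
    frame of every injected propagation delay."""
    cfg = SimConfig(n_cells=25, n_sources=5, n_edges=5, noise_sigma=0.0,
                    duration_s=240.0, frame_rate=20.0,
                    background_rate_per_min=0.0, seed=21)
    rois, truth, traces = simulate_field(cfg)
    dff = compute_dff(traces)
    from gliowave.coactivity import LagEngine
    eng = LagEngine(dff.dff, 500, cfg.frame_rate)
    idx = {c: k for k, c in enumerate(traces.cell_ids)}
    for _, e in truth.true_edges.iterrows():
        lc = eng.correlate(idx[e["cell_a"]], idx[e["cell_b"]])
        err = abs(abs(lc.best_lag) / cfg.frame_rate - e["delay_s"])
        assert err <= 1.0 / cfg.frame_rate


def test_out_of_window_speeds_are_rejected_downstream():
    """Couplings planted at 30–40 μm/s all fail the physiological speed gate."""
    from gliowave import all_pairs, detect_peaks
    cfg = SimConfig(n_cells=20, n_sources=4, n_edges=4,
                    speed_range_um_s=(30.0, 40.0), duration_s=180.0,
                    frame_rate=20.0, background_rate_per_min=0.0, seed=8)
    rois, truth, traces = simulate_field(cfg)
    dff = compute_dff(traces)
    peaks = detect_peaks(dff)
    pairs = {(p.cell_a, p.cell_b): p for p in all_pairs(dff, rois, peaks)}
    for edge in truth.edge_set():
        if edge in pairs:
            assert pairs[edge].verdict == "excluded"
            assert pairs[edge].reason == "speed"
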