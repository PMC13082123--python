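# Methods

## Scope and model

`gliowave` infers functional co-activity networks from single-cell calcium
recordings of glioma cell ensembles (and, by construction, any similar
fluorescence trace set). The pipeline takes a frames × cells fluorescence
matrix with its sampling rate and an ROI centroid table (μm), and produces an
undirected graph whose nodes are active cells and whose edges are cell pairs
with statistically significant, physiologically plausible co-activity.

The chain is:

1. **ΔF/F** — per cell, ΔF/F(t) = (F(t) − F₀)/F₀ with F₀ a low percentile of
   the trace (optionally after background subtraction).
2. **Peaks and the activity gate** — prominence-gated local maxima of ΔF/F;
   only cells with ≥ 4 peaks over the recording ("active cells") enter the
   network analysis.
3. **Connectivity strength** — for each active pair, the Pearson correlation
   of the two ΔF/F traces at every integer frame lag τ ∈ [−L, +L]; the
   maximum r across lags is the pair's connectivity strength, and the lag at
   the maximum τ\* gives the implied propagation speed v = d/|τ\*| from the
   centroid distance d.
4. **Physiological gates** — pairs are excluded when d > 100 μm, when v lies
   outside the closed window [4, 25] μm/s (a zero-lag pair has no defined
   speed and is excluded by the same gate), or when either cell is below the
   activity gate. Violations are recorded in that order, first match wins.
5. **Surrogate null** — for each gate-passing pair, one trace is rotated by a
   random offset ΔT > 5 min and the maximal lagged correlation recomputed on
   the same lag grid; pooled over pairs and draws, the 95th percentile of
   these surrogate maxima is the significance threshold r₀.
6. **Network** — an edge joins a gate-passing pair with r ≥ r₀. Summaries:
   communicating cells (degree ≥ 1, as a % of active cells), hubs (top 5% of
   the degree distribution), periodic cells (rhythmic event trains), and the
   population event rate in peaks · min⁻¹ · (100 cells)⁻¹.

A separate module scores triple-readout knockdown screens
(z = (X − μ_negctrl)/sd_population per plate and readout) and implements the
tumour-microtube morphometric gate (length > 10 μm strict, calibre
0.5–2.5 μm inclusive) and the EdU proliferation index.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| baseline percentile q | 20 | – | global per cell; rolling (30 s) variant for drift |
| baseline pre-smoothing | 1.0 | s | see "Numerical choices" |
| peak prominence multiplier k | 3 | σ̂ | σ̂ = 1.4826·MAD(diff ΔF/F)/√2 |
| peak refractory interval | 1.0 | s | minimum separation between peaks |
| detection smoothing | 0.25 | s | see "Numerical choices" |
| activity gate | 4 | peaks | per recording |
| distance gate d_max | 100 | μm | pair exclusion |
| speed window | [4, 25] | μm/s | closed interval |
| max lag L | d_max/v_min = 25 | s | smallest grid containing every admissible delay |
| surrogate shift floor ΔT_min | 300 | s | ΔT ~ uniform over (ΔT_min, T) |
| surrogates per pair | 20 | – | pooled globally |
| null percentile | 95 | – | linear-interpolation definition |
| hub fraction | 0.05 | – | of the degree distribution, ties included |
| periodicity | CV ≤ 0.3, ≥ 4 peaks | – | CV of inter-peak intervals |

The lag grid default is deliberate: at d_max = 100 μm and v_min = 4 μm/s the
longest physiologically admissible delay is 25 s, so the grid can never clip
a gate-passing edge.

## The synthetic-data generator

Since the pipeline's correctness can only be judged against known ground
truth, the simulator is first-class, tested code. It emulates the recording
geometry the analysis is designed for: a 10-min recording at 40 Hz of 50
cells placed uniformly (min separation 10 μm) in a 400-μm square field. A
subpopulation of **source cells** (default 10) fires rhythmically — period
20 s with a ±15% per-source spread and 5% per-event jitter — and drives
couplings to receiver cells at speeds drawn from [6, 20] μm/s over distances
of 20–100 μm, each event crossing an edge with probability 0.9. Remaining
cells fire sparse Poisson background events (0.2 min⁻¹), so genuinely
inactive cells (< 4 peaks / 10 min) occur. Fluorescence is rendered as
F = F₀·(1 + ΔF/F) with a fast-indicator difference-of-exponentials kernel
(rise 0.05 s, decay 0.5 s, peak-normalised amplitude 1.0 ΔF/F) evaluated at
exact sub-frame event offsets, plus Gaussian noise (σ = 0.1 ΔF/F, i.e.
amplitude SNR 10; an optional linear bleach term is off by default).

Deliberate modelling choices:

* **Star-forest coupling graph.** Each coupling joins a source to a distinct,
  previously uncoupled non-source cell. Chains and shared-receiver motifs
  would make "ground-truth edges" ill-defined as a recovery target: two
  receivers of one source are genuinely co-active at the difference of their
  delays, and any correct method would (rightly) connect them. With a star
  forest, recovered-edge precision and recall are meaningful.
* **Distinct source periods.** Two rhythmic cells sharing a period are
  synchronized by construction even with no coupling; the ±15% period spread
  keeps uncoupled sources statistically independent over a 10-min recording.
* **What is not modelled**: photobleaching beyond the optional linear term,
  motion artifacts, neuropil/background contamination, calcium buffering and
  indicator saturation, cell overlap, and non-stationary firing rates.
  Passing tests therefore demonstrate algorithmic correctness under clean,
  stationary conditions — not robustness to every imaging pathology.

Everything is a pure function of the config including its integer seed;
layout, event generation and rendering consume independent child streams of
`numpy.random.SeedSequence(seed)`, and the analysis-side null model uses a
stream spawned from the run seed, so changing the number of surrogates never
perturbs the simulated data.

## Numerical choices

**Exact per-lag Pearson by FFT.** Each lag's correlation uses only the
overlapping samples, normalised by that overlap's own means and variances
(zero-padding would bias r toward 0 at large lags). Cross-products for all
lags come from one FFT cross-correlation; overlap sums and sums of squares
come from prefix sums. Traces are globally mean-centred first, which leaves
every per-overlap Pearson unchanged but avoids cancellation in the FFT
products. The result matches a naive per-lag loop to ~1e−12 at 24 000 frames
(the test suite enforces ≤ 1e−10 at full scale).

**Degenerate overlaps.** A lag whose overlap has (numerically) zero variance
in either trace is undefined and skipped; a pair undefined at every lag is
excluded as inactive. The variance floor is 1e−12 of the trace's mean-square
per overlap sample.

**Tie-breaking.** The best lag is the smallest |τ| among lags within 1e−9 of
the maximal r, with the negative lag preferred on exact ±τ ties. The
tolerance keeps analytically exact ties (periodic signals) from being split
by float rounding.

**Detection smoothing.** Peak candidates are taken on a 0.25-s boxcar-smoothed
copy of ΔF/F. At 40 Hz, raw white noise produces hundreds of local maxima per
10-min trace whose prominence exceeds 3σ̂ (measured ≈ 380 at σ = 0.1), which
would make every cell "active"; after the 0.25-s smoothing, noise-only traces
yield zero false peaks while the ≥ 0.5-s transients lose < 10% amplitude. σ̂
is always estimated on the unsmoothed trace, so the threshold keeps its
units.

**Baseline pre-smoothing.** The F₀ percentile is taken on a 1-s
boxcar-smoothed copy of the trace. On an unsmoothed noisy trace the 20th
percentile sits ≈ 0.84 noise-sd below the true baseline, inflating every
ΔF/F amplitude by the same fraction (≈ 8% at the simulator's default noise);
smoothing suppresses the bias to the percent level. This is the
smoothed-running-percentile convention familiar from suite2p-style pipelines.
Both smoothing windows are config fields and can be set to 0.

**Circular surrogate shifts.** The surrogate rotates one trace circularly.
With a 10-min recording and ΔT > 5 min, a truncating shift would discard
over half the data; the rotation preserves length, mean, variance and
autocorrelation structure exactly, which is the stated purpose of the null.
A truncating variant is available (`NullConfig.mode = "truncate"`). One
consequence: rotating *both* traces together changes the per-lag r only
through the wrapped overlap boundary, so the relative-shift invariance is
exact for the circular alignment set and holds to a small tolerance for the
overlap-normalised statistic (tested at |Δr| < 0.05 on smooth traces).

**Percentiles.** The null threshold and the hub-degree cutoff both use
numpy's linear-interpolation percentile, so the two quantile rules are
consistent. Hub ties at the cutoff are all included; isolates are never
hubs. In sparse networks where most communicating cells have degree 1, the
cutoff can land on 1 and the tie rule then flags all of them — a documented
consequence of tie inclusion, not a bug.

**Zero-lag pairs** have no defined speed and fail the speed gate. A
synchrony-based edge rule (co-events within 100 μm and a 1-s window, no
speed gate) exists as an explicit preset, `GateConfig.synchrony_1s()`, and
is never silently merged with the default procedure.

**Degenerate pipelines.** With < 2 active cells the pair stage returns empty
with a warning; with no gate-passing pairs the threshold is undefined (NaN)
and the network is edgeless rather than an error, so ablated/silent fields
flow through the pipeline.

## Validation design and problem sizes

The validation suite runs the full method at the recording geometry above:
oracle equivalence of the correlation engine on 100 independent 10-min pairs;
null calibration pooled over 20 independent-cell fields (≈ 1 300 pair-tests;
the calibration fields use a 1.5 min⁻¹ background rate so cells are active,
and no sources, since shared rhythms would confound a false-positive count);
known-graph recovery and noiseless delay errors over 20 fields; the
source-ablation contrast over 10 paired fields; and exact arithmetic checks
for the screen and morphometry formulas. The acceptance script
(`scripts/acceptance.py`) recomputes the same quantities on freshly seeded
fields (12/12/8 fields for calibration/recovery/ablation) and writes them as
JSON.

## Known limitations

* The null threshold is pooled globally across pairs (a per-pair mode
  exists); strongly heterogeneous cell activity would make a pooled
  threshold conservative for quiet pairs and liberal for busy ones.
* Edges are undirected; the sign of the best lag is reported but not used to
  orient propagation.
* The periodicity rule (inter-peak-interval CV) is a simple rhythmicity
  proxy; an autocorrelation-based alternative is stubbed behind config but
  the CV rule is the tested default.
* The simulator propagates events a single hop from each source (the star
  forest); multi-hop relay dynamics are out of scope.
* Trace extraction (segmentation, ROI selection, motion correction) is out
  of scope; the pipeline starts at extracted traces.
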