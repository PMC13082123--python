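# gliowave

Functional co-activity network inference for calcium imaging of glioma cell
ensembles — and a ground-truth simulator to validate every stage.

Glioma cells connect into tumour networks through ultralong membrane
protrusions (tumour microtubes) and coordinate via intercellular calcium
waves. Recordings of such ensembles pose a concrete statistical question:
given per-cell fluorescence traces and cell positions, which cell pairs are
*functionally coupled*, as opposed to incidentally similar? `gliowave`
implements the standard analysis chain for this question, for researchers
who have extracted single-cell traces (e.g. from Fiji/suite2p ROIs) and want
a reproducible, tested network readout.

## The method

For each cell, ΔF/F = (F − F₀)/F₀ with F₀ a low percentile of the trace.
Cells with ≥ 4 detected calcium peaks are "active". For every active pair
(i, j) with centroid distance d:

* **connectivity strength** r = max over lags τ ∈ [−L, L] of the Pearson
  correlation of the two ΔF/F traces offset by τ (overlap-normalised);
* **propagation speed** v = d/|τ\*| from the lag τ\* at the maximum;
* **physiological gates**: the pair is discarded if d > 100 μm, if v lies
  outside [4, 25] μm/s, or if either cell is inactive;
* **significance**: each trace pair is compared against a linear-shift
  surrogate null — one trace circularly rotated by a random ΔT > 5 min,
  destroying coupling while preserving autocorrelation. The 95th percentile
  r₀ of the pooled surrogate maxima is the edge threshold, and the network
  keeps edges with r ≥ r₀.

The graph over active cells then yields the count-based summaries used for
such networks: **communicating cells** (degree ≥ 1, % of active cells),
**hubs** (top 5% of the degree distribution), **periodic cells** (rhythmic
trains, low inter-peak-interval CV), and the population event rate in
peaks · min⁻¹ · (100 cells)⁻¹.

Because real recordings of this kind are rarely public, the package ships a
seeded simulator (`gliowave.synthetic`) producing fields with known layout,
coupling graph, propagation delays and noise, so edge recovery, null
calibration and delay estimation are all testable against ground truth. A
`screen` module implements plate-wise knockdown-screen scoring
(z = (X − μ_negctrl)/sd_population per readout) with loss-of-function
ranking across three readouts, plus tumour-microtube morphometrics and the
EdU proliferation index.

## Worked example

```bash
python analysis/01_simulate_fields.py
python analysis/02_network_analysis.py
```

The first script writes a simulated 10-min, 40-Hz field of 50 cells (10
rhythmic source cells driving 10 couplings at physiological speeds) plus an
ablated twin with the sources silenced. The second runs the full analysis on
the intact field and prints:

```
cells: 50  active: 22
pairs computed: 231  excluded: {'speed': 14, 'distance': 188}
threshold r0 = 0.214 (95th pct of 580 surrogates)
edges: 10  communicating: 90.9%  hubs: 20  periodic: 15
event rate: 126.6 peaks/min/100 cells
edge recovery vs ground truth: precision 1.00 recall 1.00 F1 1.00
```

Reading this: 22 of 50 cells cleared the ≥4-peak activity gate (the sparse
background cells are genuinely inactive); of the 231 active pairs, the
distance and speed gates removed 202; the surrogate null put the
significance threshold at r₀ = 0.214; and the 10 surviving edges are exactly
the 10 planted couplings. The remaining drivers check the null's
false-positive calibration (`03`, ≈ 5% by construction), the
source-ablation contrast (`04`, communicating cells collapse from ~75% to
~0% when the rhythmic hubs are silenced), and screen scoring (`05`, a
planted triple-readout hit ranks first).

The same workflow is available as a CLI:

```bash
gliowave simulate --out data/ --seed 1
gliowave analyze --traces data/traces.csv --rois data/rois.csv --out run/ --seed 1
gliowave screen --plates plates.csv --out scored/
gliowave compare --report-a run_a/report.json --report-b run_b/report.json
```

## Layout

```
src/gliowave/        library: traces, coactivity, nullmodel, network,
                     synthetic, screen, pipeline, io, config, cli
analysis/            numbered narrative drivers writing to results/
scripts/acceptance.py  from-scratch recomputation of headline quantities
tests/               pytest suite (unit, property and pipeline-level)
docs/methods.md      model, parameters, numerical choices, limitations
```
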