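# cncorr — cell–nucleus correlation analysis of single-cell migration

`cncorr` quantifies the motility of mesenchymal-like cells from time-lapse
centroid tracks of each cell *and its nucleus*. Mesenchymal migration is
built from two independent subcellular activities: leading-edge
**protrusion** (the cell centroid advances while the nucleus stays put) and
trailing-edge **detachment** (actomyosin contraction releases the rear and
the nucleus translocates coherently with the cell body). Because these two
activities leave distinct signatures in the relative motion of cell and
nucleus, their per-interval classification reveals *how* a cell migrates —
not just how far — and yields a motility index that can be measured from a
one-hour movie of ~20 cells instead of the ten-hour recordings that
persistent-random-walk fitting requires.

The package is aimed at quantitative cell biologists and image-analysis
pipelines that already produce paired centroid tracks (any segmentation
front-end will do; `cncorr` starts from a plain CSV of positions).

## The method

For each sampling interval τ, the cell-centroid displacement (CCD) sets a
transient reference direction and the concurrent nucleus-centroid
displacement (NCD) is projected onto it, giving the signed scalar NCD_//.
The polar angle of the point (NCD_//, CCD),

θ = atan2(CCD, NCD_//) ∈ (0°, 180°],

classifies the interval's dominant activity:

| Region | θ range        | mode                             | colour |
|--------|----------------|----------------------------------|--------|
| I      | 0° < θ ≤ 45°   | detachment                       | red    |
| II     | 45° < θ ≤ 75°  | mixed detachment/protrusion      | yellow |
| III    | 75° < θ ≤ 105° | protrusion/retraction            | blue   |
| IV     | 105° < θ ≤ 180°| large-angle side protrusion      | green  |
| V      | (noise filter) | stationary mode                  | black  |

The time-ordered labels form a **barcode** of the cell's migration. The
**Cell Migration Potential Index** accumulates the effective nuclear
translocation:

CMPI = Σ_{i ∈ {I, II}} o_i · ⟨NCD_//⟩_i   (µm per interval),

where o_i is region i's occurrence fraction and ⟨NCD_//⟩_i the mean nuclear
projection within it. Intervals indistinguishable from pure positioning
noise can be relabelled Region V by a Monte-Carlo test against the
empirical fixed-cell noise distribution p(NCD_//, CCD).

For cross-validation, `cncorr` also fits the persistent-random-walk model
to mean-squared displacements via Levenberg–Marquardt on the Fürth
equation ⟨r²⟩ = 2S²P[t − P(1 − e^{−t/P})], reporting the rms speed S,
persistence time P and diffusion coefficient μ = S²P/2. An exact
Ornstein–Uhlenbeck simulator (no discretisation bias), a scripted-event
simulator with ground-truth labels, and a fixed-cell jitter simulator
provide synthetic data for every pipeline stage.

## Worked example

Simulate 15 persistent-random-walk tracks at the canonical parameters
(S = 1 µm/min, P = 10 min, 600 one-minute steps) and recover the motility
parameters from their pooled MSD:

```sh
$ cncorr simulate prw --out prw.csv --seed 42 --n 600 --tracks 15
$ cncorr prw-fit --in prw.csv
{
  "S_um_per_min": 0.9955174951086455,
  "P_min": 11.600894159957669,
  "mu_um2_per_min": 5.748562562676436,
  ...
  "converged": true
}
```

The fitted S ≈ 1.00 µm/min and P ≈ 11.6 min recover the generating values
within sampling error; μ ≈ 5.7 µm²/min estimates the analytic
S²P/2 = 5 µm²/min.

Run the CN-correlation pipeline on a scripted mixed-event cell (30%
detachment, 30% mixed, 30% protrusion, 10% turns; one-hour movie at 1-min
intervals):

```sh
$ cncorr analyze --in events.csv --tau 1 --out cn.csv
$ cncorr barcode --in cn.csv --out bc.png
demo: I=26.7%  II=26.7%  III=41.7%  IV=5.0%
$ cncorr cmpi --in cn.csv --window 10
demo: CMPI = 0.5262 um/interval (tau = 1 min, n = 60)
demo: running CMPI (10 intervals) min 0.2836 max 0.7454
```

The occurrence rates mirror the scripted event mix (detachments land in
Region I, mixed events in II, protrusions in III, turns in IV), the
whole-track CMPI of 0.53 µm/interval summarises the effective nuclear
advance per minute, and the 10-minute running CMPI resolves the more and
less motile phases of the hour.

Other subcommands: `cncorr filter` (Monte-Carlo stationary-mode
relabelling against a fixed-cell noise table), `cncorr cmpi-converge`
(sample-size convergence of ⟨CMPI⟩), `cncorr noise-sweep`
(noise-implemented CMPI vs injected σ), `cncorr simulate events|prw|fixed`.
Every operation is equally available as a library function; see
`docs/methods.md` for the model details and design choices.

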