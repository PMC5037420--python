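# Methods

This note documents the models, conventions and numerical choices behind
`cncorr`, and what the synthetic-data tests do and do not establish about
real microscopy data.

## CN-correlation geometry

Inputs are paired 2-D centroid tracks (cell, nucleus) on a uniform time
grid of spacing τ minutes, in micrometres with arbitrary origin. For each
interval (stride 1, overlapping) the cell-centroid displacement vector
defines a transient reference direction; its magnitude is the CCD and the
signed projection of the nucleus-centroid displacement onto it is NCD_//.
All downstream statistics depend only on (NCD_//, CCD), which makes them
invariant under global rotation and translation of both tracks and
equivariant under spatial rescaling — properties enforced by tests.

The classification angle is θ = atan2(CCD, NCD_//), i.e. NCD_// is the
abscissa and CCD the ordinate of the correlation plane. With CCD > 0,
θ ∈ (0°, 180°). Region brackets are half-open with closed upper bounds:
θ = 45°, 75°, 105° belong to Regions I, II, III respectively. The choice
of axes places pure protrusion (NCD_// ≈ 0) at 90° (Region III), strong
coherent detachment (NCD_// > CCD > 0) below 45° (Region I), and
nucleus-opposed turning (NCD_// < 0) above 105° (Region IV), matching the
biological reading of each mode.

**Degenerate intervals.** If CCD = 0 (within 1e-12 µm) the reference
direction does not exist; the interval is labelled UNDEFINED, drawn as a
gap in barcodes and excluded from every occurrence denominator. With
continuous-valued centroid data this is a measure-zero event; it occurs in
practice only for synthetic tracks with scripted stationary intervals or a
noiseless fixed cell.

## CMPI

CMPI = Σ_{i∈{I,II}} o_i ⟨NCD_//⟩_i, with o_i the occurrence fraction over
*defined* intervals and ⟨NCD_//⟩_i the arithmetic mean within region i
(empty region: o_i = 0, mean set to 0). Algebraically this equals the mean
over all defined intervals of NCD_// restricted to θ ≤ 75°; the identity
is asserted to 1e-12 in tests and the array-only form is used inside the
noise-sweep hot loop. Units are µm per interval at the stated τ; reports
carry τ, and an optional `cmpi_per_min` property divides by τ for cross-τ
comparison. Since θ ≤ 75° with CCD > 0 implies NCD_// > 0, CMPI is
non-negative by construction, and a cell whose nucleus never moves scores
exactly 0 (all its defined intervals sit at θ = 90°).

The population summary ⟨CMPI⟩ is the unweighted mean of per-cell CMPI
values with SEM = sd/√n; a pooled-intervals variant (`pooled_cmpi`) is
exposed for sensitivity checks, because with unequal interval counts per
cell the two differ. The four-region scheme is the default for CMPI;
Region V intervals (five-region scheme) stay in the denominator but can
never contribute to Regions I/II.

`convergence_curve` draws s cells without replacement from the pool
(default step 5, 200 iterations per size) and reports the mean of
subsample means and the mean subsample SEM, flagging the smallest s with
SEM < 10% of the mean. For a between-cell coefficient of variation around
0.35–0.40 the flag lands near 15–20 cells, the basis of the "about 20
cells suffice" guidance.

## Stationary-mode (Region V) filter

A chemically fixed cell provides a pure sample of the acquisition system's
positioning error. Its CN points are histogrammed over the (NCD_//, CCD)
plane (default 32×32 bins over the data hull) and the counts are
normalised by the maximum bin, giving a noise score p ∈ [0, 1] with the
mode at 1. Max-normalisation is a deliberate interpretation: a noise
*density* can exceed 1 and cannot serve directly as an acceptance
probability, whereas the max-normalised score reads "a displacement
indistinguishable from the most probable pure-noise outcome is almost
surely noise". The score is piecewise-constant (no interpolation);
queries outside the hull return 0; a value on an interior bin edge belongs
to the lower-index bin, and the two outermost edges are inclusive.

The Monte-Carlo filter draws one uniform deviate per interval in time
order from a single seeded RNG stream — u > p keeps the original label,
u ≤ p relabels to Region V — so reruns with the same seed are
bit-identical, the expected reassignment fraction equals the mean of p
over the series (binomial calibration, tested at n = 10⁴), and the filter
can only map I–IV to V, never between I and IV. UNDEFINED intervals
consume their draw but keep their label. Isolated V intervals are expected
during normal locomotion; `prolonged_stationary_segments` extracts runs
strictly longer than 5 intervals (at 1-min sampling, more than five
minutes) as genuine stationary episodes.

Histogram binning was preferred over kernel density estimation because it
is deterministic, cheap, and requires no bandwidth choice; with ≥100
fixed-cell points (warning threshold) the 32×32 grid resolves the noise
cloud at σ ≈ 0.17 µm well.

## Persistent random walk

The Fürth MSD ⟨r²⟩(t) = 2S²P[t − P(1 − e^{−t/P})] is fitted by
unweighted Levenberg–Marquardt least squares on the raw MSD, with
S₀ = √(MSD at first lag)/τ and P₀ = 5τ. S enters squared, so a
sign-flipped optimum is folded back; P ≤ 0 or optimizer failure yields a
non-converged result with diagnostics rather than a silent NaN, and
P beyond 10× the fitted lag window is flagged as poorly constrained
(near-ballistic data). μ = S²P/2 (two dimensions) is set from the fitted
parameters, exactly.

Time-averaged MSDs use overlapping start frames by default and lags up to
10% of the track duration. The 10% cap is the package's own choice: MSD
estimates at longer lags average few effectively independent displacement
pairs, and because the MSD grows with lag those noisy values dominate an
unweighted fit. At the reference recovery conditions (15 tracks of 600
one-minute steps, S = 1 µm/min, P = 10 min) the 10% window recovers P
within 30% on nearly all seeds, whereas a 25% window fails more often
than it succeeds. A 25% window and `weight_by_pairs` weighting remain
available as arguments. MSDs of one cell type are averaged across tracks
(`average_msd`) before fitting, so S, P, μ describe the type; per-track
fitting remains possible by fitting each curve separately.

## Synthetic data generators

`simulate_prw` draws velocities from the stationary Ornstein–Uhlenbeck
law (per-component variance S²/2, so ⟨|v|²⟩ = S² in 2-D) and advances
position and velocity jointly from the *exact* Gaussian transition of the
integrated OU process. Per component and step of length τ, with
a = e^{−τ/P}:

- E[v′|v] = a v, Var(v′) = (S²/2)(1 − a²)
- E[Δx|v] = v P (1 − a)
- Var(Δx) = S²P²[τ/P − 2(1 − a) + (1 − a²)/2]
- Cov(Δx, v′) = (S²P/2)(1 − a)²

so the ensemble MSD equals the Fürth form at every lag with no Euler
bias, making the closed form an exact oracle (tests require agreement
within Monte-Carlo error, 5% at 10⁴ tracks). The log-log MSD slope tends
to 2 for lags ≪ P and 1 for lags ≫ P, which the ballistic (P = 10⁵ min)
and Brownian (P = 0.01 min) limits of the simulator reproduce.

`simulate_events` executes a per-interval event script with a persistent
heading φ. Defaults: cell step 1 µm; detachment moves the nucleus 1.5×
the cell step along φ (the nucleus, being smaller than the whole-cell
footprint, translates farther than the area centroid during rear
release); mixed moves it 0.5×; protrusion/retraction leave it static;
turns rotate the heading by 150° while the nucleus makes a 0.4× inertia
step along the old heading. The turn parameters were set so the turn
signature is unambiguous: NCD_// = −0.4·cos 30° ≈ −0.35 per unit step
gives θ ≈ 109°, safely inside Region IV, whereas a shallower/weaker turn
(e.g. 135° with a 0.3 fraction) would fall just short of the 105°
boundary and read as protrusion. Optional isotropic positional jitter
(default 0) models localisation error.

`simulate_fixed_cell` is a constant point plus i.i.d. per-axis Gaussian
jitter (independent for cell and nucleus), the model behind the
σ ≈ 0.16–0.17 µm per-axis positioning error of a typical epifluorescence
setup; `estimate_intrinsic_sigma` recovers σ per axis as the positional
standard deviation.

**What the generators do not emulate.** Real cells have correlated event
sequences (persistence of protrusion direction, refractory periods),
heterogeneous step sizes, shape-dependent centroid coupling, and drift or
vibration noise that is neither white nor isotropic. Passing tests
therefore establish the *correctness of the computations* under the
stated models and the qualitative behaviours (event separability, noise
response, convergence rates), not the biological accuracy of any absolute
CMPI value. Absolute CMPI scales are only comparable within one τ and one
acquisition system.

## Noise robustness

Injected noise is added to the *displacement* vectors (independent 2-D
Gaussian, per-component sd σ, for cell and nucleus separately), not to
positions: displacement-level noise keeps consecutive intervals
independent, which matches the repeat-and-average protocol of the noise
sweep; position-level noise (available as `inject_position_noise`) would
anticorrelate consecutive displacements. σ = 0 bypasses the perturbation
entirely and is bit-exact. The per-component convention means the noise
vector magnitude is Rayleigh with mode σ.

`noise_implemented_cmpi` repeats inject → CN series → per-cell CMPI →
⟨CMPI⟩ (default 1000 repeats) and averages. Because isotropic noise
pushes θ toward the sin θ/2 law of a 3-D isotropic Gaussian polar angle —
under which Regions I/II carry positive NCD_// mass — large σ biases
⟨CMPI⟩ upward; the sweep quantifies when that bias matters relative to
the intrinsic error of a given microscope (≈0.17 µm per axis for the
reference system). `robustness_grid` subsamples 1-min tracks to
τ ∈ {1, 2, 3, 5, 10} min (lag-k reading, identical to re-reading every
k-th frame — tested), recomputes noise-implemented ⟨CMPI⟩ per cell type,
and reports the R² of the ordinary least-squares (intercept included)
⟨CMPI⟩-vs-μ fit across ≥3 types.

## Numerical conventions and degenerate inputs

- Uniform time spacing enforced to 1e-9 relative tolerance; the time
  column is authoritative, frame indices are bookkeeping.
- CSV dialect: UTF-8, header, "." decimal, `%.9g` floats (round-trips to
  at least 6 decimals); one dialect only.
- Autocorrelation of CN feature series is linear (Pearson per lag) with
  pairwise exclusion of UNDEFINED intervals and a zero-variance guard
  returning 1 (a constant series is perfectly self-similar). For the
  angular series a circular statistic would be the alternative; linear
  correlation was chosen for comparability between the θ and NCD_//
  series, at the cost of treating angles as plain numbers.
- Problem sizes in the test suite and acceptance script (10⁴ oracle
  pairs, 10³ identity series, 10⁴ OU tracks for the MSD oracle, 15-track
  recovery, 50-cell pools, 1000-repeat sweeps at three σ values) were
  chosen to give Monte-Carlo error comfortably below each asserted
  tolerance while keeping a laptop-scale run.

## Known limitations

- 2-D only; three-dimensional migration would need a re-derived region
  taxonomy (the projection geometry generalises, the angular brackets may
  not).
- The barcode renderer draws one rectangle per bar; very long series
  (≫10⁴ bars) render slowly.
- The max-normalised noise score is an interpretation of the fixed-cell
  filtering idea, not a likelihood-ratio test; cells whose genuine motion
  overlaps the noise cloud are filtered conservatively (more Region V).
- PRW fitting assumes time-stationary motility; phase changes within a
  track (visible in the running CMPI) violate the model and show up as
  poor fits rather than being modelled.
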