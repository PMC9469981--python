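# Methods

This note records the models implemented in `hrtb`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A track is a sequence of cell-centroid positions (µm) at strictly
increasing times (min); the nominal frame interval is 3 min.  All
statistics use time differences only, so absolute offsets are ignored.
Ensembles intended for TAMSD analysis are conventionally filtered to
tracks of ≥ 180 min (inclusive boundary), and displacement-distribution
analyses pool only tracks at least as long as the largest analysis lag,
so every lag draws from the same track set.

## Time-averaged MSD and exponent fits

The discrete TAMSD estimator at lag Δ = k·dt is the mean of
|r(t+Δ) − r(t)|^p over all overlapping frame pairs (p = 2, and p = 4 for
the fourth-moment analogue).  All windows are used with denominator equal
to the window count; this is the standard estimator and matches the
integral definition's normalization.  The exponent α is the OLS slope of
log value against log lag; the default fit range is 3–150 min.  Lags must
be strictly shorter than the track duration for a TAMSD (at least two
windows of context), while single-axis displacement pooling accepts
duration == lag (one sample).

## Curve collapse

For lags Δ ∈ {3, 6, 15, 30, 60, 120} min the single-axis displacements
δx are rescaled to η = δx/Δ^β.  For each β on a grid (default 0.30–1.20,
step 0.005) the first-order Wasserstein distance — the integral of
|U − V| between empirical CDFs, computed by `scipy.stats.
wasserstein_distance` — is evaluated for every unordered pair of lags and
the criterion is the maximum over pairs; the reported β minimizes the
criterion (ties broken toward the smaller β, immaterial on continuous
data).  Brownian ensembles collapse at β = 0.5 and ballistic ensembles at
β = 1.0; both are exercised as controls.

## Generalized-Gaussian fit

The density is the standard normalized form
γ/(2σΓ(1/γ))·exp(−|x/σ|^γ) with the location fixed at 0 (displacements
are mean-zero by symmetry).  The MLE is computed by profiling: for fixed
γ the scale MLE has the closed form σ̂ = (γ/n·Σ|x|^γ)^{1/γ}, and the
profile log-likelihood is maximized over γ ∈ [0.2, 5] by bounded Brent
search (xatol 1e-6).  This is more robust than a joint 2-D search and is
cross-checked in the tests against `scipy.stats.gennorm.fit`.  γ = 2
recovers the normal distribution and γ = 1 the Laplace; both are
exercised with 10⁵-sample controls at a ±0.1 tolerance.

## Non-Gaussianity parameter

G(Δ) = d/(d+2) · ⟨δ⁴(Δ)⟩/⟨δ²(Δ)⟩² − 1, where the angle brackets are
ensemble means of per-track time-averaged moments of the d-dimensional
displacement magnitude.  The default is d = 3 (full 3D magnitudes); d is
exposed because single-axis conventions also appear in the literature.
G = 0 for Gaussian displacements (the 3D Brownian control must lie within
±0.05 at all analysis lags), 1 for Laplace increments in 1D, and −2/3 for
fixed-magnitude ±1 steps; the last two are asserted against their
closed-form moment ratios.

## Coarse-graining and scaled empiricals

Coarse-graining retains frame 0 and then greedily the earliest frame
whose distance from the previously retained position strictly exceeds
R (default 7.2 µm); the trailing sub-threshold segment is dropped since
it has no defined run length.  Strict inequality is chosen; the boundary
case has measure zero for continuous data.  Runs, run times and turn
angles (polar angle of consecutive run vectors, arccos of the clamped
normalized dot product) follow directly.  Per-track scaled samples
(divided by the track's own mean) average exactly 1 by construction and
are pooled across tracks; only tracks with at least one turn angle
contribute a complete (r̄, θ̄, Δt̄) triplet — tracks with a single run
contribute run samples but no triplet, since the simulator needs complete
triplets.

The threshold can be calibrated by simulating from each candidate's
empiricals and minimizing the root sum of squared differences between
simulated and input ensemble TAMSDs, compared in linear space on lags
3–150 min (the squared-error objective is taken literally; a log-space
comparison would weight short lags differently).

## Run-and-tumble simulator

Each walker inherits one complete mean triplet (joint assignment
preserves the run-length/run-time correlation that sets per-cell speed —
independent resampling would destroy it).  Draws are uniform with
replacement from the pooled dimensionless samples (empirical CDF
inversion, no smoothing: the model is deliberately data-driven).  Angles
are clipped into [0, π] when θ̄ × sample exceeds π (rare; reflection
would distort the empirical mean more than clipping).  The initial
direction is uniform on the sphere, each run draws a fresh uniform
azimuth (no chirality), and the position update
x′ = x + r·cosθ·r̂ + r·sinθ·(cosφ·e₁ + sinφ·e₂) uses a Gram–Schmidt
basis perpendicular to the previous run; run length and turn angle are
preserved to machine precision.  Event tracks are linearly interpolated
onto the frame grid (exact within runs, where velocity is constant).
The production horizon is 30000 min with analysis lags up to 1500 min;
tests and benchmarks use 2000–3000 min horizons with lags to 150–600 min,
which suffice to resolve the transient super-diffusive regime at far
lower cost.

The Fickian crossover of a simulated TAMSD curve is located by a sliding
log-log slope (window 5 lag points, tolerance 0.1 on |slope − 1|): the
crossover is the smallest window-start lag from which the slope enters
and remains within tolerance of 1.

## Superstatistical inference

Velocities are per-frame displacements (µm/frame; the 3-min interval is
absorbed into the activity unit).  The AR-1 likelihood is applied per
component with shared scalar (a, q); the parameter space (0, a_max] ×
(−1, 1) is discretized into 200 × 200 cells, with a_max = 1.05 × the
largest observed per-frame speed (the bound is data-set dependent by
construction).  The K transform floors each cell at p_min (renormalized;
p_min at or above the uniform weight is rejected as it would erase all
structure) and then applies a truncated uniform box mean of radius R_box
cells per axis, followed by global renormalization — truncation with
renormalization keeps all probability on the legal domain, and a uniform
grid is an exact fixed point.  R_box (grid cells) is distinct from the
coarse-graining threshold R (µm) despite the shared letter in common
usage.

The recursions are the standard scaled forward-backward algorithm:
grids are normalized at each step with the log-normalizers accumulated,
and each likelihood grid is max-shifted before exponentiation, which is
algebraically equivalent to log-domain arithmetic while remaining
compatible with the box convolution.  Both recursions start from uniform
priors at their respective ends; the per-time posterior is
L_t · K[α_{t−1}] · K[L_{t+1}β_{t+1}], normalized.  The log evidence is
the sum of forward log-normalizers; since priors are stored as cell
masses, the voxel measure of the discrete evidence sum is already
included.  Summaries report marginal means and central 50% credible
intervals from the piecewise-linear CDF on cell edges (a uniform marginal
on (−1, 1) yields exactly (−0.5, 0.5)).  Hyperparameters (p_min, R_box)
are chosen by maximizing the evidence over a candidate table
(empirical Bayes), using forward-only passes.

Intermediate message grids are stored in single precision (posteriors
are normalized, so the ~1e-7 relative quantization is far below the
statistical uncertainty); all accumulations are double precision.

## Synthetic generators

All generators are pure functions of seed and parameters, and record
ground truth sufficient for bit-exact regeneration.  Brownian tracks use
iid Gaussian increments with per-axis variance 2·D·dt; ballistic tracks
are straight lines at per-track speeds in random directions.  The
heterogeneous run-and-tumble generator draws per-track means from
dispersed distributions — log-normal r̄ (median 8 µm, log-sd 0.5), θ̄
uniform on [0.5, 2.5] rad, log-normal Δt̄ (median 6 min, log-sd 0.5) —
with unit-mean exponential pools for scaled run length and run time and a
unit-mean rescaled half-normal for the scaled angle.  The published
evidence for these quantities is histogram-level only, so the parametric
forms are an implementation choice, exposed in `MeanTripletSpec` and
`ShapeSpec`; the dispersion magnitudes are chosen to produce
cell-to-cell variability comparable to what intravital tracking shows.
AR-1 tracks follow the velocity recursion exactly, with the first
velocity drawn from the stationary distribution of the first segment and
positions as cumulative velocity sums.

What the generators do *not* emulate: centroid-localization noise,
temporal heterogeneity within a track (dormant/motile alternation beyond
what AR-1 schedules express), z-axis field-of-view censoring, and
cell–cell interactions.  Passing tests therefore demonstrate correctness
of the estimators and the heterogeneity mechanism, not that real tracks
satisfy the model's assumptions.

## Round-trip parameter recovery

The self-consistency check of the simulator measures empiricals from a
simulated ensemble, re-simulates from them, re-measures at the same
threshold, and compares per-track means.  One subtlety is intrinsic to
threshold coarse-graining on an interpolated frame grid: a retained point
is the first *frame* beyond R from the last retained point, which chops
runs mid-flight and biases a single measure→simulate→measure pass low on
r̄ (about ×0.83 under the default conditions).  The
measurement-simulation operator converges after one iteration, so the
recovery assertion uses generating means that are themselves measurement
outputs (one burn-in round) — the only definition under which "the
generating means" are well-posed.  Mean run length and run time are then
recovered within 15% and 10% median relative error respectively; the
mean turn angle retains a ~15–20% low bias because re-segmentation
inserts near-zero angles between chords of a split run.  This is a
property of the coarse-graining observable, not a simulator defect, and
is the reason simulated and measured tracks should always be compared
through the same measurement pipeline.

## Known limitations

- The collapse criterion is evaluated on a finite β grid; resolution is
  0.005 by default and the criterion curve is returned for inspection.
- The generalized-Gaussian fit fixes the location at zero; asymmetric
  displacement distributions (e.g. drift) would bias γ.
- Evidence comparisons are only meaningful on a fixed grid: changing
  n_a, n_q or a_max changes the discrete measure.
- The superstat activity bound tracks the largest observed speed; a
  single outlier frame stretches the activity axis and coarsens its
  resolution.
- The crossover locator assumes the curve is clean enough for a local
  slope; noisy short ensembles may never satisfy the tolerance and
  return no crossover.
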