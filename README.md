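# hrtb — heterogeneous run-and-tumble trajectory analysis

`hrtb` analyzes timestamped 3D cell trajectories of the kind produced by
long time-course intravital microscopy (e.g. haematopoietic progenitor
cells tracked in bone marrow at 3-minute intervals).  It is written for
biophysicists who want to go from a plain table of cell positions to a
quantitative statement about *how* the cells move: whether the population
is super-diffusive, whether its displacement distributions are Gaussian,
whether the anomaly can be explained by cell-to-cell heterogeneity, and
how each cell's motility parameters change over time.

## What it computes

**Anomalous-diffusion statistics.**  The central estimator is the
time-averaged mean squared displacement of track *i*,

    δ²ᵢ(Δ) = ⟨ |r(t + Δ) − r(t)|² ⟩ₜ ,

averaged over tracks and fitted as ⟨δ²(Δ)⟩ ∝ Δᵅ (α = 1 Fickian, α > 1
super-diffusive).  Displacement distributions are characterized three
ways: a scaling-collapse exponent β chosen so that the rescaled variable
η = δx/Δᵝ has the same distribution at every lag (selected by minimizing
the maximum pairwise Wasserstein distance; β = 0.5 diffusive, 1.0
ballistic); a generalized-Gaussian maximum-likelihood fit
f(x) ∝ exp(−|x/σ|^γ) whose shape γ measures tailedness (γ = 2 Gaussian,
γ = 1 Laplace); and the non-Gaussianity parameter
G(Δ) = d/(d+2)·⟨δ⁴⟩/⟨δ²⟩² − 1 (0 for Gaussian displacements).

**Data-driven heterogeneous run-and-tumble model.**  Tracks are
coarse-grained at a displacement threshold (default 7.2 µm, about one
cell diameter) and decomposed into runs (length r, duration Δt) and turn
angles θ.  Dividing each track's samples by its own means (r̄, θ̄, Δt̄)
and pooling yields dimensionless *scaled empirical distributions*; the
simulator draws from these pools and rescales by per-walker mean
triplets, reproducing the observed cell-to-cell heterogeneity without
imposing a parametric model.  Simulated ensembles extrapolate the
dynamics far beyond the experimental horizon and locate the crossover
from super-diffusion to Fickian diffusion.

**Superstatistical Bayesian inference.**  Per-frame velocities are
modeled as an AR-1 persistent random walk v_t = q_t·v_{t−1} + a_t·n_t
with slowly varying persistence q_t ∈ (−1, 1) and activity a_t.  A
grid-discretized forward-backward algorithm (default 200 × 200 cells)
with a generic two-step prior transform — a probability floor p_min plus
a uniform box convolution of radius R — yields per-time posteriors,
credible intervals, and the model evidence used to pick (p_min, R) by
empirical Bayes.

## Worked example

```python
import numpy as np
from hrtb import diffusion_stats as ds, coarse_grain as cg
from hrtb.synthetic import gen_hrtb_ensemble

# 51 heterogeneous run-and-tumble walkers, 3000 min at 3-min frames
ens, truth = gen_hrtb_ensemble(n_tracks=51, duration=3000.0, seed=42)

lags = np.arange(3.0, 150.1, 3.0)
avg = ds.ensemble_average([ds.tamsd_curve(t, lags) for t in ens])
fit = ds.fit_power_law(avg, (3, 150))
print(f"TAMSD exponent alpha = {fit.alpha:.3f} +/- {fit.fit_stderr:.3f}")

res = ds.optimize_collapse(ens, axis="x", lags=(3, 6, 15, 30, 60, 120))
print(f"collapse exponent beta = {res.beta:.3f}")

samples = ds.lagged_displacements(ens, "x", 3.0, min_duration=120.0)
gg = ds.fit_generalized_gaussian(samples)
print(f"gen-Gaussian shape gamma = {gg.gamma:.3f}")

decomps = cg.decompose_ensemble(ens, 7.2)
pers, rest = ds.split_by_persistence(decomps, 1.2)
print(f"persistent cells: {len(pers)}, less persistent: {len(rest)}")
```

prints

```
TAMSD exponent alpha = 1.133 +/- 0.008
collapse exponent beta = 0.775
gen-Gaussian shape gamma = 0.361
persistent cells: 36, less persistent: 15
```

The ensemble is transiently super-diffusive (α > 1) although every
individual walker is an ordinary run-and-tumble process — the anomaly
comes entirely from the dispersed per-track means.  β well above 0.5 and
γ well below 2 show that the displacement distributions are
correspondingly non-Gaussian with a scaling propagator, and the
turn-angle split separates the persistent sub-population driving the
effect.

The same operations are exposed on the command line (`hrtb synth`,
`hrtb tracks validate|filter`, `hrtb coarse`, `hrtb calibrate`,
`hrtb analyze`, `hrtb simulate`, `hrtb superstat`); run `hrtb --help`.

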