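# Methods

## The problem

Passive stiffness of the left-ventricular (LV) myocardium is clinically
informative but cannot be measured directly: it must be inferred by fitting a
biomechanical model of diastolic filling to imaging-derived observations —
here 24 regional circumferential strains plus the end-diastolic cavity volume
(a 25-vector `y0`).  The forward model `m(θ)` is expensive (finite-element
solves measured in hours), so this package implements the statistical
shortcut: *emulation*.  A large bank of simulations at space-filling
parameter settings is computed offline; at inference time a cheap Gaussian
process (GP) surrogate replaces the simulator inside the optimization loop.

## Constitutive model and reduced parameterization

Tissue is modelled with the invariant-based orthotropic Holzapfel–Ogden
strain-energy function

```
Ψ = a/(2b) [e^{b(I1−3)} − 1]
  + Σ_{i∈{f,s}} a_i/(2b_i) [e^{b_i(I4i−1)²} − 1]
  + a_fs/(2b_fs) [e^{b_fs I8fs²} − 1] + (K/2)(J−1)²,
```

with the fibre/sheet I4 terms active only in tension (I4 > 1) — collagen
does not bear compression — and a bulk penalty `K = 10⁶` enforcing
near-incompressibility (identically zero on the kinematically isochoric
paths used for curve evaluation).  The eight constants are not jointly
identifiable from in-vivo data, so they are grouped into four dimensionless
multipliers of literature reference values:

```
a = θ₁a₀,  b = θ₁b₀,   a_f = θ₂a_f0,  a_s = θ₂a_s0,
b_f = θ₃b_f0, b_s = θ₃b_s0,  a_fs = θ₄a_fs0, b_fs = θ₄b_fs0,
θ ∈ [0.1, 5]⁴,
```

with reference values a₀=0.22 kPa, b₀=1.62, a_f0=2.43 kPa, a_s0=0.56 kPa,
b_f0=1.83, b_s0=0.77, a_fs0=0.39 kPa, b_fs0=1.70.  The a-type constants are
interpreted in kPa throughout (the literature values are conventionally
quoted in kPa); stretch–stress curves are reported in the same unit.

Uniaxial Cauchy stress is the exact analytic derivative `σ = λ dΨ̂/dλ` of the
energy under incompressible uniaxial kinematics
`F = diag(λ, λ^{-1/2}, λ^{-1/2})` with the hydrostatic pressure eliminated by
the zero-lateral-stress condition; unit tests verify it against a central
finite-difference oracle on the energy to 1e-4 relative over λ ∈ [1.01, 1.3].

## The synthetic simulator (and what it does not emulate)

The finite-element forward model is out of scope; a deterministic lumped
stand-in maps θ to the 25 outputs:

- Each of 24 segments carries a fixed loading pressure p_j on an increasing
  grid spanning 0.5–2.0 kPa (small deterministic jitter), and a fixed fibre
  angle α_j ∈ [5°, 50°] on a stride-7 permuted ramp, emulating regional
  fibre rotation.  Decorrelating the angle profile from the load profile
  makes the segments probe distinct (stretch, angle) combinations of the
  constitutive surface.
- The segment stretch λ_j solves `σ(λ; θ, α_j) = p_j` by bracketed Brent
  root-finding on (1, 2.15] to 1e-10; the reported strain is the Green
  strain (λ²−1)/2.  The stress uses the rotated-frame invariants
  I1 = λ²+2/λ, I4f = c²λ²+s²/λ, I4s = s²λ²+c²/λ, I8fs = sc(1/λ−λ²)
  (c = cos α, s = sin α), and is verified in tests against the
  finite-difference derivative of the constitutive energy under the same
  kinematics.
- Volume is `V0·(1 + mean_j(λ_j − 1))³` with V0 = 60 mL — the simplest
  smooth monotone map that puts the 25th output on a completely different
  scale from the strains, which is what makes the Euclidean/Mahalanobis
  comparison interesting.

Design rationale.  For angles below ~54° every energy term contributes a
non-negative, θ-monotone term to the stress, so all 25 outputs are smooth
and *strictly decreasing* in every θ component (stiffer tissue deforms
less); this is checked on a grid in the tests.  The fibre-sheet coupling
multiplier θ₄ acts only through I8fs = sc(1/λ−λ²), so its influence is weak
— the locally estimated sensitivity directions of the four parameters have
pairwise cosines above 0.9 — reproducing the weak identifiability of the
real problem while keeping the inverse problem solvable (smallest Jacobian
singular value around 1e-3 of the largest).  An earlier all-fibre variant
(α ≡ 0) made θ₄ exactly inert and θ₁/θ₄ unrecoverable; the angle
heterogeneity is the minimal fix.

What a green test does *not* establish: the toy model has no geometry, no
boundary conditions, no spatially heterogeneous pressure field, and its
segments are independent given θ, unlike the coupled FE mesh.  Accuracy
numbers on this world do not transfer to the clinical problem; only the
*relative* behaviour of the methods is expected to.

Observation noise is available (per-scale Gaussian, seed-reproducible) but
defaults to zero: benchmark test sets come straight from the simulator.

## Emulation strategies

- **Output emulation**: 25 independent scalar GPs, one per output, trainable
  before any observation arrives.  The surrogate loss compares the emulated
  25-vector with y0.
- **Loss emulation**: the chosen loss is evaluated between every stored
  training output and y0, and a single scalar GP is fitted to
  {(θ_n, l_n)}; the minimized quantity is the GP predictive mean.  This is
  cheaper to train but must wait for y0.

Losses: Euclidean `‖ŷ−y0‖²/(2σ²)` (σ defaults to 1; constants that cannot
move the argmin are dropped) and Mahalanobis `½ rᵀΣ⁻¹r` with Σ the unbiased
training-output covariance plus a ridge of `1e-8·trace/J` (the strain/volume
scale gap makes Σ ill-conditioned), solved by Cholesky factorization.

## Interpolators

**Local GP** (per-query K-nearest-neighbour kriging, K = 100 by default):
ARD squared-exponential kernel with constant mean (set to the local sample
mean), noise sd initialized at 1e-2 and optimized with floor 1e-6,
hyperparameters by L-BFGS-B on the log marginal likelihood with analytic
gradients in log-parameter space.  A supplied warm start is always raced
against the default initialization (half-span length scales, sd-of-targets
output scale), because warm starts carried across the box can sit in poor
likelihood optima.  Cholesky failures escalate jitter ×10 up to 1e-2, then
raise.

Caching: refitting all 25 local GPs at every optimizer evaluation is
prohibitively slow, so the emulator keeps a small LRU cache of "regions"
(neighbour sets + factorizations), keyed by reference query; a region is
reused while the query stays within half the median nearest-neighbour
spacing of its reference.  Kernel hyperparameters are refit once per query
point by default (`hyper_tol = ∞`; configurable, and `cache_mode="exact"`
refits everything at every call).  The estimation loop compensates with a
*polish* phase: after the multistart search, the emulator is freshly refit
at the incumbent optimum and the descent re-run (up to three rounds).  This
puts the fully refit surrogate exactly where accuracy matters.

**Low-rank GP**: isotropic Matérn 3/2 kernels on θ and on τ = 1/θ
componentwise (safe since θ ≥ 0.1), each with its length scale fixed at the
maximum pairwise distance of its inputs; the two additive smooths are
realized as a single GP with the summed kernel and one shared output scale.
The unit-scale kernel matrix of a random subsample of n_r rows (default
2000, full data if smaller) is eigendecomposed once — dense `eigh` plus
top-k selection by |eigenvalue|, equivalent to a Lanczos truncation at these
sizes — and the output scale and noise sd are then estimated by maximizing
the truncated-model log marginal likelihood in O(k) per evaluation
(eigenvalues s²d_i + σ² on the retained directions, σ² on the complement).
Default ranks: k = 2000 for output targets, k = 1000 for loss targets.
Prediction uses the rank-k pseudo-inverse (weights confined to the retained
eigenbasis): energy the truncation discards inflates the estimated noise
instead of being amplified at prediction time, and at k = n_r the model is
exactly GP regression with the summed kernel (tested against a dense
oracle).  Sharing the eigenbasis across output columns (it depends only on
the design) reduces a 25-output fit to one eigendecomposition plus 25
two-parameter optimizations.

## Optimization

Bounded multistart over [0.1, 5]⁴: scrambled-Sobol starting points (default
50 at full scale; benchmark runs use fewer — see below) plus the five
training design rows whose *stored simulated outputs* best match y0 (the
training bank doubles as a scored trial-point set).  Starts are ranked
best-first; each start not inside the basin of attraction (sphere of radius
‖start − minimum‖) of an already-found minimum launches an L-BFGS-B descent
capped at 100 iterations.  Descents are *chained*: the solver is restarted
from its endpoint while it still improves by more than the configured
tolerance (relative 1e-8), because resetting the curvature memory helps
L-BFGS-B follow the long curved valleys the correlated parameters produce.
Estimates violating the hyperbox are clipped to it (L-BFGS-B is
bound-constrained, so this is a formality).

## Uncertainty quantification

At the minimum, the Hessian of the surrogate loss is estimated by central
differences with per-dimension step `1e-4·(upper−lower)`; it is symmetrized
and repaired to positive definiteness by clipping eigenvalues at
`max(1e-10·max|eig|, (10·box width)⁻²)` — the second floor caps the sd of an
unidentified direction at ten box widths, beyond which the box-truncated
distribution is indistinguishable from flat while rejection sampling stays
feasible.  The inverse is the approximate covariance (a Cramér–Rao style
lower bound).  S = 1000 samples (default) are drawn from
MVN(θ̂, H⁻¹) with rejection of draws outside the hyperbox, and mapped
through the stretch–stress evaluation to pointwise 2.5/97.5% bands on the
fibre and sheet curves; the band is widened (elementwise min/max) to contain
the point-estimate curve, so the reported interval is a guaranteed envelope.
At λ = 1 every curve is exactly zero, so the band collapses there.

## Benchmark harness

Eight methods = {output, loss} × {local GP, low-rank GP} × {Euclidean,
Mahalanobis}.  For each method and each test observation the full estimation
pipeline runs and the parameter-space MSE `¼‖θ̂−θ*‖²` (mean-of-squares
convention, documented and fixed) is recorded; distributions are summarized
by the median and quartiles under the linear-interpolation quantile
convention.  Output-strategy emulators are fitted once per interpolator and
shared across losses and test points; low-rank loss emulators share the
cached eigenbasis across observations.  Failures and non-convergent fits are
recorded (and retained in the distribution) rather than fatal.

## Scaled-down defaults and runtime

The full-scale protocol (10 000 training + 100 test points, 50 starts) is
supported but sized for a cluster.  The test suite's recovery study uses
2000 training points, the next 10 Sobol points as test observations, and 8
Sobol starts (plus the 5 trial-point starts) so the whole eight-method
comparison fits a desk-scale budget; the method ranking is insensitive to
these sizes.

## Known limitations

- The toy simulator's identifiability is engineered, not derived from LV
  physics; absolute MSE values are meaningful only within this world.
- The low-rank variance uses the pseudo-inverse spectral form; it is exact
  at full rank but only a non-negative approximation below it.
- Hessian-based intervals assume a locally quadratic surrogate loss; with
  strongly correlated parameters the MVN can be a poor description of the
  ridge geometry (profiling would be the next step).
- Per-test-point hyperparameter caching trades a small amount of surrogate
  fidelity during the global search for an order-of-magnitude speedup; the
  polish phase restores fidelity at the reported optimum but intermediate
  diagnostics (e.g. basin diagnostics) reflect the cached surface.

## A red result, on purpose

In this toy world the low-rank *loss* emulation fails for both losses at the
desk-scale configuration (N = n_r = 2000, loss rank k = 1000): the
truncation error the likelihood absorbs as noise (sd ≈ 3) exceeds the depth
of the loss basin (≈ 2 for Mahalanobis, ≈ 0.1 for Euclidean), so the
emulated surface develops spurious negative valleys deeper than the true
basin and the minimizer lands far from the truth for most test points.  The
corresponding benchmark assertion (Mahalanobis beating Euclidean within
low-rank loss emulation) is therefore expected to fail and is left failing:
the ordering between two methods that cannot resolve the basin is noise.
Raising k to the subsample size repairs the calibration, but k = 1000 is
the reference configuration for loss targets and is kept.  The local-GP
loss emulation resolves the basin and reproduces the expected ordering
comfortably.
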