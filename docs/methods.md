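# Methods

## The damage model

`pitcorr` implements a continuum-damage (CDM) description of pitting
corrosion for biodegradable Mg-alloy coupons immersed in simulated body
fluid. The coupon is discretized into identical cubic elements of edge
`Le` (mm). Each element carries a scalar damage variable `dP ∈ [0, 1]`
(0 = intact, 1 = fully corroded) that evolves only while the element is on
the corroding surface:

    ∂dP/∂t = (δu / Le) · Ku · λp        [1/h]

- `Ku` (1/h) is the kinetic constant of the underlying uniform corrosion
  process; it sets the absolute rate scale.
- `δu` (mm) is the material characteristic length and `Le` the element
  characteristic length; only their ratio enters. Default `δu = Le`, so
  the rate reduces to `Ku · λp` and `Ku` alone fixes the timescale. `δu`
  is exposed for sensitivity studies.
- `λp` (dimensionless) is an element-specific pitting multiplier. On the
  initially exposed surface it is drawn i.i.d. from a Weibull distribution
  with shape `γ` and scale `ψ` (density
  `f(x) = (γ/ψ)(x/ψ)^(γ−1) e^−(x/ψ)^γ` for `x ≥ 0`), sampled by inverse
  CDF `λ = ψ(−ln U)^{1/γ}`.

When an element reaches `dP = 1` it is removed from the mesh (true element
deletion — the voxel disappears from exported fields). Each face neighbour
of a removed element becomes exposed and inherits

    λp′ = β · λp(donor),

so `β > 1` accelerates a pit as it burrows and `β < 1` damps it back toward
uniform recession. `mode="uniform"` pins `λp ≡ 1` everywhere (inherited
values included), recovering the uniform-corrosion damage model as a
degenerate case with a closed-form recession front speed of one element per
`Le/(δu·Ku)` hours — used as an analytic oracle in the tests.

Mass loss is reported in percent of the initial coupon mass. Two
accountings are provided: `partial` (default) credits in-progress damage,
`Σ dP·V / V_tot`; `removed_only` counts deleted elements. They coincide in
the limit of instantaneous removal; `partial` gives smooth curves on coarse
meshes.

## Geometry

The disc coupon (default 15 mm diameter × 3 mm thickness) is voxelized on a
structured cubic lattice clipped to the cylinder by a centre-inside test,
with one lateral cell centred on the coupon axis. This makes `Le` exact,
element volume exactly `Le³` and face adjacency trivial, at the cost of a
jagged rim; the discretized volume converges to `πr²h` (≤ 2% error at
`Le = 0.25 mm`). When a target element count is requested the edge length
is refined by a few fixed-point rescalings; a voxelized disc cannot hit an
arbitrary count exactly, so the realized count is documented to land within
~15% (3558 elements for the 3600-element default). Coordinates: coupon axis
= z, origin at the bottom-face centre, lengths in mm, times in hours
(days × 24 at the interfaces).

## Time integration

Explicit Euler with operator splitting: a damage increment over `dt`, then
a removal/inheritance sweep. The step is adaptive,

    dt = 0.1 · Le / (δu · Ku · max active λp),

capping the fastest element's per-step damage gain at 0.1. Because the
maximum is taken over *active* (exposed, non-removed) elements, `dt`
shrinks while a fast cascade is burning and recovers as soon as the fast
elements are gone; the clock additionally lands exactly on requested
record times. Numerical details:

- `dP` is capped at exactly 1; removal triggers at `dP ≥ 1 − 1e−9`
  (accumulated 0.1-steps can sum to `1 − O(ε)` in floating point).
- Inherited `λp` is clipped at `1e12`. With `β > 1` a cascade multiplies
  `λp` geometrically and would overflow; beyond the cap an element's
  remaining lifetime is `< 1e−10 h`, far below any recorded resolution, so
  the clip is observationally neutral.
- Competing inheritance (several donors, or a donor meeting an
  already-assigned neighbour) resolves to
  `λp′ = max(current, β · max over donors)` — deterministic and
  order-independent; a pit accelerates its most-attacked path. Only the six
  face neighbours inherit; edge/corner neighbours do not.
- One seeded generator; one Weibull draw per initially exposed element in
  mesh-index order; inheritance consumes no randomness. Trajectories are
  bit-reproducible from the seed.
- Stopping: either a time horizon or a mass-loss target. A target run with
  `Ku · max λp = 0` is rejected up front; a run that stalls mid-way (e.g.
  `β = 0` freezing all newly exposed elements) raises a non-termination
  error, which the design-evaluation layer records as infinite χ².

## Calibration workflow

The four constants (γ, ψ, β, Ku) are calibrated against an immersion
mass-loss dataset:

1. **Design.** A 3-level, 4-factor Box–Behnken design over the factor box
   (defaults: γ, ψ ∈ [0.1, 5.1], β ∈ [0.1, 10.1], Ku ∈ [0.001, 0.2] with
   centres (2.6, 2.6, 5.1, 0.1005)): all six factor pairs at (±1, ±1) with
   the others at centre (24 edge runs) plus 3 centre replicates — 27 runs.
2. **Scoring.** Each run is simulated until the experimental final mass
   loss, with `reps = 3` replicate seeds derived deterministically from a
   master seed. Curves are compared on the dimensionless axis
   `τ = t / t_final`, where `t_final` is the last recorded time for the
   experiment and the first time the simulation reaches the experimental
   final mass loss. χ² = `Σ (obs − pred)² / obs` over the nonzero
   experimental points (the day-0 point would divide by zero), with the
   simulated curve linearly interpolated at the experimental τ values.
   Percent mass loss is the χ² variable.
3. **Surface.** A full 15-coefficient quadratic (4 linear, 4 quadratic,
   6 interactions, intercept) is fitted by OLS on factors coded to [−1, 1];
   coefficients are reported in coded and raw units with `t`-test p-values
   (27 − 15 = 12 df). Raw-scale responses are the default; a log-response
   fit is always computed alongside, since χ² responses can span four
   decades. Responses from unreachable runs (infinite χ²) are dropped from
   the fit with a recorded warning.
4. **Optimum.** The surrogate is minimized over the factor box with a dense
   11⁴ multistart grid (ties broken by the first/lowest flat grid index)
   plus bounded local refinement, then re-simulated to report an achieved
   χ²; if that exceeds the best design run, a surrogate-inadequacy warning
   is recorded rather than hidden.

## The pseudo-experiment generator

`synth_experiment` emulates a gravimetric immersion test: it simulates a
coupon at known parameters to a final mass loss (default 89.27%, the
packaged dataset's endpoint), samples the curve at evenly spaced
dimensionless times, adds i.i.d. Gaussian noise (default 1 percentage
point, a plausible coupon-to-coupon scatter for an n≈7 averaged assay),
clips to [0, 100], enforces monotonicity and the (0, 0) point. It emulates
*sampling* and *measurement noise* only — not corrosion-product cleaning
bias, pH drift, solution replenishment, or inter-coupon variability in
geometry. Recovery results on synthetic data therefore bound what the
calibration can do on real data from above.

## Identifiability and the β > 1 collapse

Two structural properties of the model, both verified by the test suite,
matter when interpreting any calibration with this package:

- **ψ and Ku are pure time rescalings.** Multiplying ψ (the λp scale) or
  Ku rescales every element's damage rate uniformly, so the mass-loss
  curve changes only its time axis. The dimensionless-time alignment
  removes exactly that axis; consequently χ² is invariant to ψ and Ku (to
  the random seed), and neither parameter is identifiable from a single
  mass-loss curve compared in dimensionless time. Only γ (dispersion of
  pit intensities) and β (pit acceleration) shape the curve. The
  recovery experiment in the acceptance suite documents this: γ and β are
  pulled toward the truth, ψ and Ku land anywhere in the box.
- **β > 1 causes finite-time collapse.** Once the first element is removed
  at `t₁ = 1/(Ku·max λp)` (δu = Le), inheritance multiplies λp by β per
  shell, so successive shells die geometrically faster and the entire
  connected coupon is consumed by `≈ t₁·(1 + 1/(β − 1))`. For β = 5.1 the
  simulated mass-loss curve is a slow ramp (partial damage of the initial
  surface) terminated by a near-instantaneous jump to 100%, whatever the
  mesh or step size — the collapse is a property of the exact dynamics,
  not a numerical artifact, and the adaptive step integrates it correctly.
  A sigmoidal 28-day-like curve cannot be produced at β = 5.1 under these
  dynamics; fits of this model family to smooth experimental sigmoids are
  only meaningful for β ≤ 1, or under integrators that artificially limit
  the removal-front speed (e.g. processing removal once per fixed, coarse
  time increment), in which case the fitted constants are properties of
  the integrator as much as of the material. This is documented as a known
  limitation of the model family rather than patched over, and it is why
  the packaged historical response table cannot be reproduced by this
  simulator (see the acceptance results discussion in the README).

A related consequence: at matched dimensionless time the curve is dominated
by the initially-exposed volume fraction, which depends on the mesh
(≈ 42% of elements at ~3600, ≈ 19% at ~64750 for the default coupon), so
mass-loss curves do *not* converge under refinement at fixed β > 1; the
mesh-convergence study reports this honestly.

## Problem sizes and defaults used in the shipped checks

Chosen once, as the package's own study conditions: coupon 15 × 3 mm at
~3600 elements (the historical mesh) for headline χ² checks, 10 seeds;
mesh-convergence study 3600 vs 64750 elements, 5 seeds, compared at
τ = 0.5; parameter-recovery calibration on an ~800-element coupon with
`reps = 3` and noise 1 percentage point; Weibull sampler goodness-of-fit at
n = 10⁴, KS α = 0.01.

## Known limitations

- Phenomenological: no electrochemistry, species transport, stress
  coupling, H₂ bookkeeping, or microstructure; constants must be
  recalibrated per alloy and environment.
- Disc coupons only are generated (the data model permits arbitrary voxel
  sets; no importer for external meshes is provided).
- χ² weighting by `1/observed` over-weights early, small observations;
  alternatives (RMSE, relative error) are deliberately out of scope to
  keep the calibration objective faithful to the workflow being
  reproduced.
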