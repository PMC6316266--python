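# pitcorr

Continuum-damage pitting-corrosion simulation of biodegradable Mg-alloy
coupons, with Box–Behnken / response-surface calibration against immersion
mass-loss data.

Biodegradable magnesium implants corrode away in the body; qualifying an
alloy requires predicting its in-vitro mass-loss curve. `pitcorr` is for
researchers who model that degradation phenomenologically: each finite
element of a voxelized coupon carries a damage scalar `dP ∈ [0,1]` growing
as

    ∂dP/∂t = (δu/Le) · Ku · λp,

where `Ku` (h⁻¹) is the uniform-corrosion kinetic constant, `δu/Le` a
characteristic-length ratio (default 1), and `λp` an element-specific
pitting multiplier, Weibull-distributed (shape `γ`, scale `ψ`) on the
initially exposed surface. Elements reaching `dP = 1` are deleted and their
face neighbours inherit `λp′ = β·λp`, so pits accelerate (β > 1) or damp
(β < 1). Setting `λp ≡ 1` recovers classic uniform surface recession. The
four constants (γ, ψ, β, Ku) are calibrated to an experimental mass-loss
curve by simulating a 27-run Box–Behnken design, scoring each run with
χ² = Σ(obs − pred)²/obs on a dimensionless time axis, fitting a
15-coefficient quadratic response surface, and minimizing it over the
factor box. The Mg–1.2Zn–0.5Ca immersion dataset (SBF, 37 °C, 28 days) and
the original 27-run χ² table ship as packaged fixtures.

## Worked example

```python
from dataclasses import replace
import pitcorr as pc

mesh = pc.build_coupon_mesh(diameter=15.0, thickness=3.0, target_elements=3600)
dataset = pc.builtin_mgznca_dataset()
params = replace(pc.OPTIMIZED_MGZNCA_PARAMS, seed=1)

curve = pc.simulate(mesh, params, mass_loss_target=dataset.final_mass_loss)
print(f"{mesh.n_elements} elements, "
      f"t_final = {curve.final_time_for(89.27):.2f} h, "
      f"chi2 = {pc.chi2_against_dataset(curve, dataset):.2f}")
```

prints

```
3558 elements, t_final = 1.88 h, chi2 = 62.09
```

meaning: the 15 × 3 mm coupon voxelized into 3558 cubes reaches the
experimental final mass loss (89.27%) after 1.88 simulated hours, and the
dimensionless-time χ² against the measured five-point curve is ≈ 62 — a
poor fit, see below. Running `examples/02_simulate_pitting.py` additionally
prints the observed/simulated curve point by point; the other scripts under
`examples/` each demonstrate one capability (meshing and VTK export,
uniform-recession closed form, design generation, response-surface
refitting, synthetic-data parameter recovery).

A command-line interface wraps the same functions:

```sh
pitcorr simulate --elements 3600 --seed 1 --outdir run1   # curve + VTK snapshots
pitcorr bbd                                               # 27-run design CSV
pitcorr calibrate --dataset my_mass_loss.csv --reps 3
pitcorr converge --counts 365,3600,64750
```

## What the fit means (and why the historical numbers differ)

Two structural facts, both exposed by the test suite and discussed in
`docs/methods.md`, govern any use of this model family:

- With the dimensionless-time comparison, ψ and Ku only rescale time and
  therefore cannot be identified from a single mass-loss curve; only γ and
  β shape it.
- For β > 1 the inheritance cascade is self-accelerating: after the first
  element dies the whole coupon collapses in a geometrically shrinking
  tail. At the packaged study's β = 5.1 the simulated curve is a ramp plus
  a jump, not the smooth experimental sigmoid — hence the large χ² above.
  Smooth historical curves at β > 1 can only have come from integrators
  whose coarse removal sweeps limited the front speed; the constants
  calibrated that way are tied to those unreported numerics and are not
  reproducible by a convergent integrator.

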