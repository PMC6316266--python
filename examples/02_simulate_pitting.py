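"""Simulate pitting corrosion of the Mg-1.2Zn-0.5Ca coupon at the published
optimum parameters and score the curve against the immersion experiment.

The run stops when the simulated mass loss reaches the final experimental
value (89.27%); both curves are then placed on the dimensionless time axis
tau = t / t_final and compared at the experimental sampling points with the
chi-square discrepancy sum((obs - pred)^2 / obs).
"""

import numpy as np

from pitcorr import (
    OPTIMIZED_MGZNCA_PARAMS,
    build_coupon_mesh,
    builtin_mgznca_dataset,
    chi2_against_dataset,
    simulate,
    to_dimensionless,
)
from dataclasses import replace

mesh = build_coupon_mesh(15.0, 3.0, target_elements=3600)
dataset = builtin_mgznca_dataset()
params = replace(OPTIMIZED_MGZNCA_PARAMS, seed=1)

curve = simulate(mesh, params, mass_loss_target=dataset.final_mass_loss)
aligned = to_dimensionless(curve, anchor_mass_loss=dataset.final_mass_loss)

ds = to_dimensionless(dataset)
tau = ds.dimensionless_time[1:]
pred = aligned.interp(tau)
print("tau      observed %   simulated %")
for t, o, p in zip(tau, ds.mass_loss_pct[1:], pred):
    print(f"{t:5.3f}  {o:10.2f}  {p:12.2f}")

print(f"\ntime to reach {dataset.final_mass_loss}%: "
      f"{curve.final_time_for(dataset.final_mass_loss):.2f} h")
print(f"chi-square vs experiment: {chi2_against_dataset(curve, dataset):.2f}")
print(
    "\nNote the curve shape: with beta = 5.1 > 1 every removal accelerates "
    "its neighbours multiplicatively, so once the first element corrodes "
    "away the whole coupon collapses almost instantly. The simulated curve "
    "is therefore a slow ramp (partial surface damage) ending in a jump, "
    "which is why the chi-square is large; see docs/methods.md."
)
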