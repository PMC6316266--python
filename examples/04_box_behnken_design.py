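"""Generate the 3-level, 4-factor Box-Behnken design used for calibration.

Each of the six factor pairs is pushed to its four (low/high, low/high)
corners with the other two factors at centre (24 edge runs), plus three
centre replicates: 27 runs, matching the published design table row for
row (as a multiset).
"""

from pitcorr import DEFAULT_FACTOR_RANGES, box_behnken

design = box_behnken(DEFAULT_FACTOR_RANGES, center_replicates=3)
df = design.to_frame()
print(df.to_string())
print(f"\n{design.n_runs} runs; centre point replicated "
      f"{design.center_replicates}x at (2.6, 2.6, 5.1, 0.1005).")
print("Coded units (each non-centre run touches exactly two factors):")
print(design.coded_runs()[:4])
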