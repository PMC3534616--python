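"""Calibrate a per-cycle error model from control reads and exclude cycles.

Control reads come from a variant-free reference (the role a PhiX174
spike-in plays on a real flow cell).  Three cycles are planted with elevated
error; the model's cumulative per-cycle rate flags exactly those cycles
against the 0.02% threshold, and the remaining cycles stay in play for
variant calling.
"""
import numpy as np

from poolcap import build_error_model, simulate_control_reads
from poolcap.seq import random_sequence

rng = np.random.default_rng(2)
control_ref = random_sequence(5_000_000, rng)
planted = (7, 21, 33)
# enough unique reads that the pseudocount floor sits well under the
# 0.02% exclusion threshold (see docs/methods.md on control sizing)
control = simulate_control_reads(
    control_ref,
    error_profile=1e-5,                 # quiet baseline
    elevated_cycles=[(c, 3e-4) for c in planted],
    n_reads=1_200_000,
    seed=3,
    read_length=36,
)
model = build_error_model(control, order=2)
excluded = model.excluded_cycles(threshold=0.0002)

cum = model.cumulative_cycle_error()
print("cycle  cumulative(fwd)  cumulative(rev)  excluded")
for c in range(1, model.read_length + 1):
    mark = "  <-- " if c in excluded else ""
    print(f"{c:5d}  {cum[0, c-1]:.6f}         {cum[1, c-1]:.6f}      {mark}")
print(f"\nplanted elevated cycles: {planted}")
print(f"excluded by the model:   {tuple(sorted(excluded))}")
print(f"{model.read_length - len(excluded)} of {model.read_length} cycles retained for calling")
print("\none model cell, Pr(T|C) at cycle 10 forward:",
      f"{model.error_rate(0, 10, 1, 3):.2e}")
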