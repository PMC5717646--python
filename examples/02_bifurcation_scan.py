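"""Sweep the agonist concentration L1 and track steady-state branches.

Above the fold point the system is bistable: which branch is reached
depends on history, a hysteresis in the activation readout C3.  At
high dose the bound pool saturates at min(L1, R), so the branch count
freezes instead of closing in a second fold.
"""

from pathlib import Path

import numpy as np

from tcrkp import load_params, scan_parameter

params = load_params(Path(__file__).parent / "configs/example_text_3steady.yaml")
result = scan_parameter(params, "L1", np.geomspace(1e-2, 1e2, 25))

counts = result.table.groupby("value")["count"].first()
print("L1 -> number of steady states:")
for v, c in counts.items():
    print(f"  L1={v:10.4g}  {c}")
for lo, hi in result.fold_intervals:
    print(f"fold point bracketed in L1 within [{lo:.6g}, {hi:.6g}]")
print()
print("The fold is a saddle-node where a stable branch and the saddle")
print("collide; above it the response is history dependent.")
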