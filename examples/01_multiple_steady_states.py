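"""Enumerate and classify the steady states of a bistable instance.

With three phosphorylation sites, strong SHP-1 feedback (large ST) and
slow ligand dissociation (small nu1), the model supports three positive
steady states: a weakly activated one (low S, high C3), a strongly
suppressed one (high S, low C3) and a saddle between them.
"""

from pathlib import Path

from tcrkp import classify, enumerate_steady_states, load_params

params = load_params(Path(__file__).parent / "configs/example_text_3steady.yaml")
states = enumerate_steady_states(params)

print(f"{len(states)} positive steady states (S, C0..C3):")
for ss in states:
    rep = classify(params, ss)
    coords = ", ".join(f"{c:.4f}" for c in ss.C)
    print(f"  S={ss.S:.4f}  C=({coords})  {rep.label}"
          f"  unstable-manifold dim={rep.unstable_dim}")
print()
print("S is active phosphatase, C3 the activation readout: the low-S")
print("state is the 'activated' branch, the high-S state the branch in")
print("which the feedback has shut signalling down.")
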