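"""Scan all eight interface-layer configurations and score state preference.

Each of three interface positions is a hydrogen-bond network (A) or a
hydrophobic layer (X).  Burial differences between the states feed a linear
preference score: negative favors the compact short state, positive the
extended long state.
"""

from helixswitch import (assign_layers, build_long_state, build_short_state,
                         burial_delta, default_architecture, enumerate_configs,
                         score_state_preference)

spec = default_architecture()
short = build_short_state(spec)
long_ = build_long_state(spec)

assignment = assign_layers(short)
deltas = burial_delta(short, long_, assignment)
print("per-layer interface residues (hinge-proximal first):")
for k in range(3):
    print(f"  layer {k + 1}: inner {sorted(assignment.inner[k])} "
          f"/ flipping {sorted(assignment.flipping[k])}")
print("inner-side exposure gained on extension (Å² per layer):",
      [f"{d:.0f}" for d in deltas["inner"]])

print("\nconfig  networks  score   preferred state")
for cfg in enumerate_configs():
    score = score_state_preference(cfg, deltas["inner"])
    state = "long" if score > 0 else "short"
    print(f"{cfg.code}     {cfg.n_networks}        {score:+.3f}  {state}")

print("\nMore buried networks weaken the short-state interface: only the")
print("all-network design (AAA) tips the balance to the long state, matching")
print("the qualitative behaviour of the characterized designs.")
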