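"""Classify noisy decoy structures against the two reference states.

Mimics the analysis of structure-prediction output: a pool of perturbed
models is labeled short/long/other by symmetry-aware RMSD (minimum Kabsch
RMSD over the three cyclic chain relabelings).
"""

import numpy as np

from helixswitch import (build_long_state, build_short_state,
                         default_architecture, state_fractions)
from helixswitch.state_builder import BundleModel

spec = default_architecture()
short = build_short_state(spec)
long_ = build_long_state(spec)

rng = np.random.default_rng(0)


def noised(model, scale):
    return BundleModel(
        chains={c: v + rng.normal(scale=scale, size=v.shape)
                for c, v in model.chains.items()},
        segments=list(model.segments), sequence=dict(model.sequence))


decoys = ([noised(short, 0.5) for _ in range(6)]
          + [noised(long_, 0.5) for _ in range(3)]
          + [noised(short, 25.0)])  # one garbage model

fs, fl, fo = state_fractions(decoys, short, long_, threshold=3.0)
print(f"{len(decoys)} decoys at threshold 3.0 Å:")
print(f"  fraction short = {fs:.2f}   (6 gentle short perturbations)")
print(f"  fraction long  = {fl:.2f}   (3 gentle long perturbations)")
print(f"  fraction other = {fo:.2f}   (1 heavily distorted model)")
print("\nLow-noise decoys are recovered exactly; structures far from both")
print("references land in 'other' rather than being force-assigned.")
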