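"""Tell the two states apart from solution scattering.

Computes Debye model profiles for both states, runs Guinier and normalized
Kratky analysis, then fits a noisy synthetic "experimental" profile to each
state separately — the better fit is taken as the dominant solution state.
"""

import numpy as np

from helixswitch import (build_long_state, build_short_state, debye_profile,
                         default_architecture, fit_states, guinier_fit,
                         normalized_kratky, radius_of_gyration)
from helixswitch.solution_obs import ScatteringProfile

spec = default_architecture()
models = {"short": build_short_state(spec), "long": build_long_state(spec)}
profiles = {}
for name, model in models.items():
    profile = debye_profile(model.all_ca())
    rg, i0, window = guinier_fit(profile)
    kratky = normalized_kratky(profile, rg, i0)
    profiles[name] = profile
    print(f"{name:5s}: coordinate Rg {radius_of_gyration(model.all_ca()):5.2f} Å | "
          f"Guinier Rg {rg:5.2f} Å | Kratky peak at qRg = {kratky.peak_x:.2f} "
          f"(height {kratky.peak_y:.2f})")

print("\nA compact globule peaks near qRg = 1.73; elongation pushes the peak")
print("right — the long state's larger peak position reports its extension.")

rng = np.random.default_rng(1)
truth = profiles["long"]
noisy = ScatteringProfile(q=truth.q, I=truth.I * (1 + 0.02 * rng.normal(size=len(truth))),
                          sigma=0.02 * truth.I + 1e-12)
fit = fit_states(noisy, profiles["short"], profiles["long"])
print(f"\nsynthetic 2%-noise data from the long state:")
print(f"  chi(short) = {fit['short']['chi']:.2f}   chi(long) = {fit['long']['chi']:.2f}"
      f"   -> dominant state: {fit['dominant']}")
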