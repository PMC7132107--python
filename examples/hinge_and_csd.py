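"""Hinge tuning: ion-site geometry and NMR chemical-shift deviations.

The key hinge residue's three symmetric copies can frame an ion coordination
site in the long state but not the short state, so an aspartate or histidine
there can bias the equilibrium.  Combined chemical-shift deviations quantify
per-residue differences between two solution states.
"""

from helixswitch import (build_long_state, build_short_state, check_ion_site,
                         csd_amide, csd_methyl, default_architecture,
                         mutate_hinge)

spec = default_architecture()
print(f"parent hinge window: {spec.hinge_sequence}{spec.backup_residue} "
      f"(residues {spec.hinge_start}-{spec.backup_hinge_index})")

for variant in ("GVDQ", "GGHN"):
    mutated = mutate_hinge(spec, variant)
    print(f"variant {variant}: hinge {mutated.hinge_sequence}, "
          f"backup {mutated.backup_residue}")

for state, build in (("long", build_long_state), ("short", build_short_state)):
    model = build(spec)
    report = check_ion_site(model, spec.key_hinge_index)
    print(f"{state:5s} state ion site at residue {spec.key_hinge_index}: "
          f"feasible={report.feasible} (triad radius {report.triad_radius:.2f} Å, "
          f"window {report.coordination_distance_window})")

print("\ncombined chemical-shift deviations (ppm):")
print(f"  methyl dH=0.10, dC=0.20 -> CSD {csd_methyl(0.10, 0.20):.4f}")
print(f"  amide  dH=0.10, dN=0.50 -> CSD {csd_amide(0.10, 0.50):.4f}")
print("\nA coordination-competent triad must place all three pseudo-atoms")
print("2.2-3.0 Å from their common axial centroid; only the extended state's")
print("converged hinge achieves this.")
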