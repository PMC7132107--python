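# Methods

## Scope and intent

helixswitch is a coarse-grained, CA-level model of a two-state homotrimeric
helical-bundle design scheme.  It reproduces the *geometry and logic* of the
scheme — two divergent ground states built from one architecture, interface
layers that tune the preference between them, a hinge whose turn/helix
character selects the state — without any molecular-mechanics energy
function.  Structure prediction, rotamer-level network search, and sequence
optimization are outside its scope; where the original workflow used such
tools, this package substitutes transparent geometric criteria and says so
below.

## Backbone model

Helices are generated from the Crick parameterization: a minor helix of
radius r₁ (default 2.26 Å), twist ω₁ (default 100°/residue) and phase φ₁,
wound on a superhelical axis of radius r₀, twist ω₀ and phase φ₀, rising
Δz (default 1.51 Å) per residue along the C3 axis (+z).  All lengths are in
Å, angles in degrees, and angle wrapping follows (−180, 180].  With r₀ = 0
and ω₀ = 0 the trace is a straight ideal α-helix; consecutive CA–CA
distances are then 3.78 Å.

`fit_crick` inverts the generator by Levenberg–Marquardt least squares with
multi-start over a fixed grid of helical phases (8 values) and both twist
handednesses, initialized from moment estimates (mean z-slope for Δz, mean
squared xy radius for r₀, unwrapped azimuthal drift for ω₀).  On clean
generated traces the round trip recovers every parameter to better than
1e-3 of its unit; the superhelical phase of a near-straight helix (r₀ ≈ 0)
is intrinsically unidentifiable and only r₀ itself is meaningful there.
Non-convergence raises a fit error carrying the best residual.

ABEGO torsion bins are: O when |ω| < 90° (cis peptide, highest precedence);
for φ < 0, A when −75° ≤ ψ < 50° and B otherwise; for φ ≥ 0, G when
−100° ≤ ψ < 100° and E otherwise.  The boundaries are conventional choices
consistent with the qualitative region definitions (α, β, positive-φ
helix/strand, cis) and live in one constants table.

## Default architecture and its calibration

The default two-state architecture uses straight idealized helices
(ω₀ = 0): an idealized approximation that keeps every geometric contract
analytic while retaining the full supercoiled machinery for user-supplied
parameters.  Frozen values, chosen once so that the built states meet the
~66 Å / ~100 Å height targets and all packing constraints, then never
revisited:

| quantity | value | rationale |
|---|---|---|
| inner helix | 44 res, r₀ = 5.0 Å | inner ring spans the short-state height |
| outer helix | 28 res, r₀ = 11.5 Å, azimuth +30° | upper outer ring, top 1.5 Å below the inner top |
| hinge | 3 res (GGG), residues 73–75 | three-glycine hinge; key residue 75, backup 76 |
| flipping helix | 21 res | longer flipping helices separate the states' scattering |
| short-state flipping placement | r = 12.2 Å, azimuth −20°, antiparallel | folds back against the inner helices without clashing with the outer ring |
| long-state extension coil | r = 5.5 Å | three flipping helices pack as a trimeric coiled coil (axes 9.5 Å apart) |
| long-state hinge rise | 2.2 Å/res | hinge spiral clears the inner-helix tops |

The exact superhelical parameters of the parent bundles are not public, so
these defaults are approximations calibrated to the printed heights; the
built defaults measure 67.4 Å (short) and 101.6 Å (long).

**Long-state hinge geometry.**  The hinge carries helical (α) torsion
metadata and the flipping-helix axis is parallel to the outer-helix axis,
but the hinge CA path jogs radially inward (outer ring → extension-coil
radius, ending at 5.0 Å from the axis).  This simultaneously satisfies three
constraints that a literal straight continuation cannot: the flipping axes
stay within 15° of the outer axis, the three flipping helices approach
within 12 Å of each other, and the key hinge residue's three copies converge
near the axis — which is also where the experimentally characterized long
state places its ion-coordinating hinge residues.

**Short-state turn.**  The turn is closed from a fixed library of ABEGO
turn templates (all letter combinations of the hinge length except all-A),
each realized as an ideal CA path via pseudo-bond geometry (bond 3.8 Å;
per-letter pseudo-angle/dihedral: A 91°/50°, B 120°/−170°, G 91°/−50°,
E 120°/170°).  The template whose attachment point lands closest to the
rigidly placed flipping helix wins, provided its path stays clash-free;
closure fails with an error when the hinge endpoints are farther apart than
hinge_len × 3.8 Å.  This replaces the original database lookup of
helix-turn-helix motifs with a deterministic, dependency-free equivalent.
The default architecture selects an A–E–A turn (one non-helical bin, as a
turn must have).

**Clash and contact thresholds** (one table in `constants.py`): CA–CA clash
2.5 Å (cross-chain pairs plus within-chain pairs ≥3 residues apart);
flipping–inner contact < 10 Å in the short state; flipping–flipping approach
< 12 Å in the long state; axis-angle limits 15° (long, vs outer) and 150°
(short, vs inner); interface contact cutoff 9 Å.

## Ion-coordination site

`check_ion_site` places a pseudo side-chain atom 2.4 Å from each
symmetry-related CA toward the axis (a CA-only proxy for a short polar side
chain) and declares the site feasible iff the three pseudo-atoms' centroid
lies on the C3 axis (tolerance 0.5 Å) and each atom falls within the
coordination window, default [2.2, 3.0] Å — mimicking Ca²⁺–O coordination
distances.  In the default long state the key hinge residue sits 5.0 Å from
the axis, giving a triad radius of 2.6 Å (feasible); in the short state the
same residue sits ~10 Å out (infeasible).  Both the window and the proxy
offset are caller parameters.

## Interface layers and state preference

`assign_layers` finds inner/flipping CA contacts within 9 Å in one monomer
of the short state, slices the contact zone into three equal z-slabs ordered
hinge-proximal first (boundary ties go to the lower-index layer), and
excludes the first flipping residue, which belongs to the hinge window.  The
assignment is defined on the short state and reused for the long state.

Residue identities: A layers put asparagine (network core) on the inner side
and Ser/Thr support on the flipping side; X layers use Leu/Ile/Val graded by
position.  SASA is Shrake–Rupley (via biotite) with a 1.4 Å probe, 960
sphere points, and uniform 3.0 Å pseudo-residue radii — validated against
the analytic sphere area to 2%.

The state-preference score is a deliberately transparent linear proxy for
the original energy-based ranking: each A layer contributes
+w_A·d (networks weaken the short-state interface and are partially exposed
in the long state), each X layer −w_X·d, where d is the layer's share of
the inner-side burial change between states (uniform 1/3 when no burial
deltas are supplied).  Position weights (hinge-proximal first)
w_A = (0.9, 0.7, 0.5) and w_X = (4.2, 4.0, 3.8) were calibrated once
against the four experimentally observed states (XXA/XAX/XAA short, AAA
long) and frozen; the score is monotone in the number of networks, XXX is
the most short-favoring, and zero weights give zero score.  `polar_triad_check`
is the geometric stand-in for network validation: a cyclic triad qualifies
when all three pairwise pseudo-atom distances fall in [2.6, 3.2] Å.

## State classification

`symmetric_rmsd` is the minimum Kabsch RMSD over the three cyclic chain
relabelings; only cyclic mappings are searched because the chains are
oriented N→C, so anti-cyclic mappings would align reversed chains.
Superposition uses proper rotations only (det = +1).  `classify_state`
labels a structure by the nearer reference when that RMSD is within the
threshold (default 3.0 Å over CA atoms — the original "resembles" cutoff is
not public, so this is an exposed parameter), with ties and distant
structures labeled "other".

## Solution observables

Debye profiles use a constant per-CA form factor (default 1) and no
solvent/excluded-volume term: only the *relative* discrimination of the two
states is needed, not absolute atomistic scattering.  The default q grid is
0–0.4 Å⁻¹ with 201 points.  Missing uncertainties default to 1% of I(q),
floored at 1e-12.

Guinier fits iterate the window until q_max·Rg ≤ 1.0 is self-consistent
(seeded by a fit over the whole curve; at least 5 points are required).
The conventional 1.3 cutoff overestimates Rg truncation bias on these
elongated bundles (2.7% error on the short state vs 1.4% at 1.0), so 1.0 is
the package default and the cutoff remains a parameter.  Normalized Kratky
curves are (qRg)²·I/I0 vs qRg with the peak refined by a local cubic
spline; the ideal-globule reference peak (√3, 3/e) is reproduced to 1e-6.

`fit_states` computes the closed-form optimal scale per model profile,
χ² normalized by N−1, and calls the lower-χ state dominant — mirroring the
simplifying assumption that the better single-state fit represents the
dominant solution species.  An equal mixture of both profiles yields χ
values within a factor of two of each other, i.e. no confident call.

CSD formulas are exactly Δδ_CH3 = [½(Δδ_H² + Δδ_C²/4)]^½ and
Δδ_NH = [½(Δδ_H² + Δδ_N²/25)]^½ (ppm).

## Synthetic fixtures

`generate_fixtures(seed, ...)` emulates the study inputs the package cannot
ship: reference PDBs for both states, decoys with 0.5 Å isotropic CA noise
(five per state), SAXS profiles with 2% multiplicative Gaussian noise, and a
per-residue shift table whose hinge/flipping rows carry larger differences
(σ 0.15 ppm ¹H) than the static base (σ 0.02 ppm), reflecting that the
moving segments feel the conformational change.  Outputs are byte-identical
for identical seeds.  What passing the closed-loop tests shows: the
pipeline recovers its own states under the stated noise.  What it does not
show: performance on real crystallographic/NMR ensembles, whose deviations
are correlated and segment-dependent rather than isotropic, nor absolute
SAXS accuracy, since the Debye model omits hydration-layer effects.

## Problem sizes and numerical choices

Default models are 96 residues/chain (288 CA per trimer); all analyses run
in seconds on one CPU.  The Crick round-trip property is exercised on 100
random well-conditioned parameter sets (r₀ 3–8 Å, ω₀ −4…−1°/res, seeded).
Coordinates serialize at PDB precision (3 decimals); internal computation is
double precision (biotite's SASA returns float32).  Degenerate inputs are
errors, not silent results: empty models, rank-deficient superpositions,
non-overlapping q ranges, sub-5-point Guinier windows.

## Known limitations

- CA-only geometry: no side chains, no energies; "hydrogen-bond network"
  and "ion site" checks are distance criteria on pseudo-atoms.
- The default architecture is an idealized straight-helix approximation of
  the parent supercoiled bundles, calibrated to the two printed heights;
  its layer residue indices are not claimed to match the real designs
  residue-for-residue.
- The preference score is an ordinal proxy: calibrated to reproduce the
  observed state ordering, not to predict free-energy differences.
- Register shifts induced by bound ions, domain-swapped crystal forms, and
  calcium-dependent aggregation are not modeled.
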