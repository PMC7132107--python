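"""Frozen numerical constants.

Everything tunable that the rest of the package treats as fixed lives here:
ideal-helix geometry, ABEGO bin boundaries, clash/contact thresholds, the
default two-state architecture, and the calibrated interface-preference
weights.  Values are set once and referenced everywhere else; tests assert
behaviour, not these numbers.
"""

import numpy as np

# ---------------------------------------------------------------------------
# Ideal alpha-helix geometry (canonical values)
# ---------------------------------------------------------------------------
IDEAL_RISE = 1.51          # Å per residue along the helix axis
IDEAL_TWIST = 100.0        # degrees per residue
IDEAL_CA_RADIUS = 2.26     # Å, CA distance from the helix axis
CA_CA_BOND = 3.8           # Å, consecutive CA pseudo-bond length

# Helical (alpha) backbone torsions used for hinge metadata
HELICAL_PHI = -57.0
HELICAL_PSI = -47.0
TRANS_OMEGA = 180.0

# ---------------------------------------------------------------------------
# ABEGO torsion bins.  O takes precedence (cis omega); A/B need phi < 0,
# G/E need phi >= 0.  Boundaries are conventional choices consistent with the
# qualitative region definitions (alpha, beta, positive-phi helix/strand, cis).
# ---------------------------------------------------------------------------
ABEGO_CIS_OMEGA_MAX = 90.0      # |omega| below this -> O
ABEGO_A_PSI_MIN = -75.0         # phi < 0 and psi in [min, max) -> A
ABEGO_A_PSI_MAX = 50.0
ABEGO_G_PSI_MIN = -100.0        # phi >= 0 and psi in [min, max) -> G
ABEGO_G_PSI_MAX = 100.0

# Representative (phi, psi) per ABEGO letter, used for turn-template torsions
ABEGO_CANONICAL_TORSIONS = {
    "A": (-57.0, -47.0),
    "B": (-120.0, 135.0),
    "G": (60.0, 40.0),
    "E": (120.0, -170.0),
}

# CA-trace pseudo-geometry per ABEGO letter: (pseudo bond angle, pseudo
# dihedral) in degrees, used by the turn-template builder.
ABEGO_CA_PSEUDO = {
    "A": (91.0, 50.0),
    "B": (120.0, -170.0),
    "G": (91.0, -50.0),
    "E": (120.0, 170.0),
}

# ---------------------------------------------------------------------------
# Geometry thresholds (one table, per the module contracts)
# ---------------------------------------------------------------------------
CLASH_CA_CA = 2.5               # Å, any closer CA pair is a clash
LONG_FLIP_AXIS_MAX_ANGLE = 15.0  # deg, flipping vs outer axis in the long state
SHORT_FLIP_AXIS_MIN_ANGLE = 150.0  # deg, flipping vs inner axis in the short state
LONG_FLIP_APPROACH_MAX = 12.0   # Å, min inter-chain flipping CA distance (long)
SHORT_FLIP_INNER_MAX = 10.0     # Å, min flipping-to-inner CA distance (short)

# Ion-coordination-site defaults (Ca2+ -- O like window)
ION_WINDOW = (2.2, 3.0)         # Å
ION_PROXY_OFFSET = 2.4          # Å, pseudo side-chain offset from CA toward axis
ION_AXIS_TOL = 0.5              # Å, centroid must sit this close to the C3 axis

# Hydrogen-bond triad geometry (polar network stand-in)
TRIAD_DISTANCE_WINDOW = (2.6, 3.2)  # Å, pairwise donor/acceptor distances

# ---------------------------------------------------------------------------
# Default two-state architecture.  Residue counts and placement radii were
# calibrated once so the built models reproduce the ~66 Å (short) and ~100 Å
# (long) axial heights and satisfy the packing contracts, then frozen.
# Residue numbering puts the hinge at 74-76 with key residue 75 and backup 76.
# ---------------------------------------------------------------------------
INNER_N_RES = 44
OUTER_N_RES = 28
DEFAULT_FLIP_LEN = 21           # flipping-helix length (second design round)
DEFAULT_HINGE_LEN = 3           # hinge length (second design round)
DEFAULT_HINGE_SEQ = "GGG"       # glycine hinge
DEFAULT_BACKUP_RESIDUE = "T"    # residue just after the hinge (GGGT window)

INNER_RADIUS = 5.0              # Å, superhelical radius of the inner ring
OUTER_RADIUS = 11.5             # Å, superhelical radius of the outer ring
OUTER_AZIMUTH = 30.0            # deg, outer helix azimuth offset from inner
OUTER_TOP_DROP = 1.5            # Å, outer-helix top below the inner-helix top

# Short state: the flipping helix folds back alongside the inner helices
SHORT_FLIP_RADIUS = 12.2        # Å
SHORT_FLIP_AZIMUTH = -20.0      # deg, relative to the monomer's inner helix
SHORT_FLIP_PHASE = 180.0        # deg, helical phase of the folded-back helix
SHORT_FLIP_TOP_Z_OFFSET = -1.5  # Å, flipping N-terminus below the outer top

# Long state: the three flipping helices extend as a trimeric coiled coil
LONG_FLIP_RADIUS = 5.5          # Å, extension coiled-coil radius
LONG_HINGE_RISE = 2.2           # Å per hinge residue, clears the inner tops

# ---------------------------------------------------------------------------
# Interface layers
# ---------------------------------------------------------------------------
LAYER_CONTACT_CUTOFF = 9.0      # Å, CA-CA cutoff defining interface contacts
N_LAYERS = 3

# Residue identity tables.  A layers place an asparagine network core on the
# inner side with Ser/Thr support on the flipping side; X layers use branched
# hydrophobics graded by layer position (hinge-proximal first).
A_LAYER_INNER = "N"
A_LAYER_FLIP = ("S", "T", "S")
X_LAYER_INNER = ("L", "I", "V")
X_LAYER_FLIP = ("L", "L", "I")

# State-preference score weights (hinge-proximal first), calibrated once
# against the observed states of XXA/XAX/XAA (short) and AAA (long), frozen.
SCORE_W_A = (0.9, 0.7, 0.5)
SCORE_W_X = (4.2, 4.0, 3.8)

# ---------------------------------------------------------------------------
# SASA (coarse-grained Shrake-Rupley)
# ---------------------------------------------------------------------------
SASA_PROBE_RADIUS = 1.4         # Å
SASA_N_POINTS = 960
SASA_CA_RADIUS = 3.0            # Å, uniform pseudo-residue radius

# ---------------------------------------------------------------------------
# Solution observables
# ---------------------------------------------------------------------------
DEFAULT_Q_GRID = np.linspace(0.0, 0.4, 201)   # Å^-1
GUINIER_QMAX_RG = 1.0   # conservative window: the bundles are elongated
SIGMA_DEFAULT_FRACTION = 0.01   # missing sigma -> 1% of I(q)
SIGMA_FLOOR = 1e-12

# State classification
CLASSIFY_THRESHOLD = 3.0        # Å, default "resembles" cutoff over CA atoms
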