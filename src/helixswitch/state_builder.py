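"""Construction of short- and long-state C3 trimer backbones.

A two-state architecture consists of a six-helix-bundle base (three inner and
three outer helices), a short hinge, and a mobile "flipping" helix per chain.
In the compact short state (~66 Å tall) the flipping helices fold back through
a turn hinge and pack alongside the inner helices; in the extended long state
(~100 Å) the hinge takes helical torsions and the three flipping helices
extend past the top of the bundle, converging into a trimeric coiled coil.
The key hinge residue of the three chains then meets near the symmetry axis,
where it can form an ion coordination site — a feature absent in the short
state.

Models are coarse-grained CA traces; hinge torsions are carried as metadata
so the turn/helix character of the hinge is explicit and ABEGO-classifiable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import constants as C
from .errors import ClashError, ClosureError, ParameterError, ResidueLookupError
from .geometry import (CrickParams, TorsionTriple, apply_c3, generate_helix,
                       rotation_about_z)

__all__ = [
    "ArchitectureSpec",
    "BundleModel",
    "IonSiteReport",
    "default_architecture",
    "build_short_state",
    "build_long_state",
    "measure_height",
    "check_ion_site",
    "mutate_hinge",
    "global_clash_check",
    "segment_axis",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
CHAIN_IDS = ("A", "B", "C")
SEGMENTS = ("base_inner", "base_outer", "hinge", "flipping")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Full description of a two-state design.

    ``key_hinge_index`` is the residue whose three symmetric copies can form
    the long-state ion site (G75 in the default numbering); the backup
    residue (T76) is the first flipping residue, i.e. the last letter of the
    four-letter hinge window used by :func:`mutate_hinge`.
    """

    inner_helix: CrickParams
    outer_helix: CrickParams
    flipping_helix_len: int = C.DEFAULT_FLIP_LEN
    hinge_len: int = C.DEFAULT_HINGE_LEN
    hinge_mode: str = "turn"
    hinge_sequence: str = C.DEFAULT_HINGE_SEQ
    backup_residue: str = C.DEFAULT_BACKUP_RESIDUE
    key_hinge_index: int | None = None
    backup_hinge_index: int | None = None
    layer_positions: tuple | None = None

    def __post_init__(self):
        if not (2 <= self.hinge_len <= 7):
            raise ParameterError(f"hinge_len must be in [2, 7], got {self.hinge_len}")
        if self.flipping_helix_len < 8:
            raise ParameterError(
                f"flipping_helix_len must be >= 8, got {self.flipping_helix_len}")
        if self.hinge_mode not in ("turn", "helical"):
            raise ParameterError(f"hinge_mode must be turn|helical, got {self.hinge_mode!r}")
        if len(self.hinge_sequence) != self.hinge_len:
            raise ParameterError("hinge_sequence length must equal hinge_len")
        for aa in self.hinge_sequence + self.backup_residue:
            if aa not in AMINO_ACIDS:
                raise ParameterError(f"invalid amino-acid letter {aa!r}")
        if self.key_hinge_index is None:
            object.__setattr__(self, "key_hinge_index", self.hinge_end)
        if self.backup_hinge_index is None:
            object.__setattr__(self, "backup_hinge_index", self.key_hinge_index + 1)
        if not (self.hinge_start <= self.key_hinge_index <= self.hinge_end):
            raise ParameterError("key_hinge_index must fall inside the hinge segment")
        if not (self.hinge_start <= self.backup_hinge_index <= self.hinge_end + 1):
            raise ParameterError(
                "backup_hinge_index must fall inside the hinge window (hinge + 1)")

    # 1-based residue bookkeeping (per chain, continuous through the hinge)
    @property
    def hinge_start(self) -> int:
        return self.inner_helix.n_res + self.outer_helix.n_res + 1

    @property
    def hinge_end(self) -> int:
        return self.hinge_start + self.hinge_len - 1

    @property
    def n_res(self) -> int:
        return self.hinge_end + self.flipping_helix_len

    def to_dict(self) -> dict:
        d = {
            "inner_helix": vars(self.inner_helix).copy(),
            "outer_helix": vars(self.outer_helix).copy(),
            "flipping_helix_len": self.flipping_helix_len,
            "hinge_len": self.hinge_len,
            "hinge_mode": self.hinge_mode,
            "hinge_sequence": self.hinge_sequence,
            "backup_residue": self.backup_residue,
            "key_hinge_index": self.key_hinge_index,
            "backup_hinge_index": self.backup_hinge_index,
            "layer_positions": ([sorted(s) for s in self.layer_positions]
                                if self.layer_positions else None),
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["inner_helix"] = CrickParams(**d["inner_helix"])
        d["outer_helix"] = CrickParams(**d["outer_helix"])
        if d.get("layer_positions"):
            d["layer_positions"] = tuple(frozenset(s) for s in d["layer_positions"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        return cls.from_dict(json.loads(text))


@dataclass
class BundleModel:
    """Annotated CA-level coordinates of a C3 trimer.

    ``chains`` maps chain id to an (n_res, 3) CA array; ``segments`` labels
    every residue (shared across chains); ``hinge_torsions`` records the
    torsion triple assigned to each hinge residue during construction.
    """

    chains: dict[str, np.ndarray]
    segments: list[str]
    sequence: dict[str, str]
    state_tag: str = "unknown"
    hinge_torsions: list[TorsionTriple] = field(default_factory=list)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_res(self) -> int:
        return len(self.segments)

    def all_ca(self) -> np.ndarray:
        return np.concatenate([self.chains[c] for c in self.chains], axis=0)

    def segment_indices(self, segment: str) -> np.ndarray:
        """1-based residue indices belonging to a segment."""
        return np.array([i + 1 for i, s in enumerate(self.segments) if s == segment])

    def residue_ca(self, chain_id: str, resnum: int) -> np.ndarray:
        """CA position of a 1-based residue on one chain."""
        try:
            chain = self.chains[chain_id]
        except KeyError:
            raise ResidueLookupError(f"no chain {chain_id!r}") from None
        if not (1 <= resnum <= len(chain)):
            raise ResidueLookupError(f"residue {resnum} missing on chain {chain_id}")
        return chain[resnum - 1]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "BundleModel":
        rot = np.eye(3) if rotation is None else rotation
        tr = np.zeros(3) if translation is None else np.asarray(translation)
        return BundleModel(
            chains={k: v @ rot.T + tr for k, v in self.chains.items()},
            segments=list(self.segments),
            sequence=dict(self.sequence),
            state_tag=self.state_tag,
            hinge_torsions=list(self.hinge_torsions),
        )


@dataclass(frozen=True)
class IonSiteReport:
    """Geometric feasibility of a C3 ion coordination site."""

    feasible: bool
    triad_radius: float
    centroid_z: float
    coordination_distance_window: tuple[float, float]


# ---------------------------------------------------------------------------
# Default architecture
# ---------------------------------------------------------------------------

def default_architecture() -> ArchitectureSpec:
    """The frozen default two-state architecture.

    A 44-residue inner helix and 28-residue outer helix (straight idealized
    bundle, inner ring 5 Å, outer ring 11.5 Å), a three-glycine turn hinge at
    residues 73-75 with key residue 75 and backup residue 76, and a
    21-residue flipping helix.  Calibrated once so the built short and long
    states are ~66 and ~100 Å tall.
    """
    inner = CrickParams(r0=C.INNER_RADIUS, omega0=0.0, omega1=C.IDEAL_TWIST,
                        phi0=0.0, phi1=0.0, n_res=C.INNER_N_RES)
    outer_span = (C.OUTER_N_RES - 1) * C.IDEAL_RISE
    inner_top = (C.INNER_N_RES - 1) * C.IDEAL_RISE
    outer = CrickParams(r0=C.OUTER_RADIUS, omega0=0.0, omega1=C.IDEAL_TWIST,
                        phi0=C.OUTER_AZIMUTH, phi1=0.0,
                        z_offset=inner_top - outer_span - C.OUTER_TOP_DROP,
                        n_res=C.OUTER_N_RES)
    return ArchitectureSpec(inner_helix=inner, outer_helix=outer)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _default_sequence(spec: ArchitectureSpec) -> str:
    seq = ["A"] * spec.n_res
    for k, aa in enumerate(spec.hinge_sequence):
        seq[spec.hinge_start - 1 + k] = aa
    seq[spec.hinge_end] = spec.backup_residue  # first flipping residue
    return "".join(seq)


def _segments(spec: ArchitectureSpec) -> list[str]:
    return (["base_inner"] * spec.inner_helix.n_res
            + ["base_outer"] * spec.outer_helix.n_res
            + ["hinge"] * spec.hinge_len
            + ["flipping"] * spec.flipping_helix_len)


def _assemble(spec: ArchitectureSpec, monomer: np.ndarray, state_tag: str,
              hinge_torsions: list[TorsionTriple]) -> BundleModel:
    chains = dict(zip(CHAIN_IDS, apply_c3(monomer)))
    model = BundleModel(chains=chains, segments=_segments(spec),
                        sequence={c: _default_sequence(spec) for c in CHAIN_IDS},
                        state_tag=state_tag, hinge_torsions=hinge_torsions)
    clashes = global_clash_check(model)
    if clashes:
        raise ClashError(
            f"{state_tag}-state model has {len(clashes)} CA clash(es) < "
            f"{C.CLASH_CA_CA} Å, e.g. {clashes[0]}", residues=clashes)
    return model


def global_clash_check(model: BundleModel,
                       threshold: float = C.CLASH_CA_CA) -> list[tuple]:
    """Return CA pairs closer than ``threshold``.

    All cross-chain pairs are checked; within a chain, pairs separated by
    fewer than three residues are bonded neighbours and exempt.
    """
    ids = model.chain_ids
    clashes = []
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            d = cdist(model.chains[ids[a]], model.chains[ids[b]])
            if a == b:
                n = d.shape[0]
                ii, jj = np.triu_indices(n, k=3)
                close = d[ii, jj] < threshold
                for i, j in zip(ii[close], jj[close]):
                    clashes.append(((ids[a], int(i) + 1), (ids[b], int(j) + 1)))
            else:
                ii, jj = np.nonzero(d < threshold)
                for i, j in zip(ii, jj):
                    clashes.append(((ids[a], int(i) + 1), (ids[b], int(j) + 1)))
    return clashes


def segment_axis(coords: np.ndarray) -> np.ndarray:
    """Unit axis of a helical segment, oriented N -> C."""
    pts = np.asarray(coords, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def axis_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = float(np.clip(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1))
    return float(np.degrees(np.arccos(cosang)))


def _cylindrical(r: float, az_deg: float, z: float) -> np.ndarray:
    t = np.deg2rad(az_deg)
    return np.array([r * np.cos(t), r * np.sin(t), z])


def _step_azimuth(r1: float, r2: float, dz: float, step: float) -> float:
    """Azimuthal increment (deg) so a cylindrical step has length ``step``."""
    xy_sq = step**2 - dz**2
    if xy_sq <= 0:
        return 0.0
    cos_daz = (r1**2 + r2**2 - xy_sq) / (2 * r1 * r2)
    return float(np.degrees(np.arccos(np.clip(cos_daz, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Long state
# ---------------------------------------------------------------------------

def build_long_state(spec: ArchitectureSpec) -> BundleModel:
    """Build the extended state: the hinge takes helical torsions and the
    flipping helices continue past the bundle top as a trimeric coiled coil.

    The hinge CA path carries the chain from the outer-helix top inward to
    the extension coil radius; its final (key) residue sits close enough to
    the axis for the three symmetric copies to frame an ion site.
    """
    inner = generate_helix(spec.inner_helix)
    outer = generate_helix(spec.outer_helix)

    start = outer[-1]
    r_start = float(np.hypot(start[0], start[1]))
    az = float(np.degrees(np.arctan2(start[1], start[0])))
    z = float(start[2])

    # hinge: spiral inward toward the ion-site radius while rising steeply
    # enough to clear the inner-helix tops
    r_end = 5.0
    hinge_pts = []
    r_prev = r_start
    for k in range(1, spec.hinge_len + 1):
        r_k = r_start + (r_end - r_start) * k / spec.hinge_len
        dz = C.LONG_HINGE_RISE
        az += _step_azimuth(r_prev, r_k, dz, C.CA_CA_BOND)
        z += dz
        hinge_pts.append(_cylindrical(r_k, az, z))
        r_prev = r_k
    hinge = np.array(hinge_pts)

    # flipping helix: vertical extension coil; its first CA sits one CA step
    # beyond the hinge end
    dz0 = 1.4
    first_ca_radius = C.LONG_FLIP_RADIUS + spec.outer_helix.r1
    az += _step_azimuth(r_prev, first_ca_radius, dz0, C.CA_CA_BOND)
    flip_params = CrickParams(r0=C.LONG_FLIP_RADIUS, omega0=0.0,
                              omega1=C.IDEAL_TWIST, phi0=az, phi1=0.0,
                              r1=spec.outer_helix.r1, delta_z=C.IDEAL_RISE,
                              z_offset=z + dz0, n_res=spec.flipping_helix_len)
    flipping = generate_helix(flip_params)

    monomer = np.concatenate([inner, outer, hinge, flipping], axis=0)
    torsions = [TorsionTriple(C.HELICAL_PHI, C.HELICAL_PSI, C.TRANS_OMEGA)
                for _ in range(spec.hinge_len)]
    return _assemble(spec, monomer, "long", torsions)


# ---------------------------------------------------------------------------
# Short state: ABEGO turn templates
# ---------------------------------------------------------------------------

def _nerf_step(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
               length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place the next point given three predecessors (natural extension)."""
    theta = np.deg2rad(angle_deg)
    tau = np.deg2rad(dihedral_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-length * np.cos(theta),
                  length * np.sin(theta) * np.cos(tau),
                  length * np.sin(theta) * np.sin(tau)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def _turn_templates(hinge_len: int) -> list[str]:
    letters = "ABGE" if hinge_len <= 5 else "ABG"
    combos = ["".join(c) for c in itertools.product(letters, repeat=hinge_len)]
    return [c for c in combos if set(c) != {"A"}]


def _turn_candidates(outer: np.ndarray, hinge_len: int) -> list[tuple[str, np.ndarray, np.ndarray]]:
    out = []
    for template in _turn_templates(hinge_len):
        pts = [outer[-3], outer[-2], outer[-1]]
        ok = True
        for letter in template:
            theta, tau = C.ABEGO_CA_PSEUDO[letter]
            try:
                pts.append(_nerf_step(pts[-3], pts[-2], pts[-1], C.CA_CA_BOND, theta, tau))
            except (ZeroDivisionError, FloatingPointError):
                ok = False
                break
        if not ok:
            continue
        theta, tau = C.ABEGO_CA_PSEUDO["A"]
        probe = _nerf_step(pts[-3], pts[-2], pts[-1], C.CA_CA_BOND, theta, tau)
        out.append((template, np.array(pts[3:]), probe))
    return out


def build_short_state(spec: ArchitectureSpec) -> BundleModel:
    """Build the compact state: a turn hinge folds the flipping helix back
    against the inner helices (antiparallel), keeping the ~66 Å height.

    The turn is closed with a fixed library of ABEGO turn templates; the
    template minimizing the attachment mismatch to the rigidly placed
    flipping helix wins.  Raises :class:`ClosureError` when the hinge
    endpoints are farther apart than ``hinge_len * 3.8`` Å.
    """
    if spec.hinge_mode != "turn":
        raise ParameterError("build_short_state requires hinge_mode='turn'")
    inner = generate_helix(spec.inner_helix)
    outer = generate_helix(spec.outer_helix)

    outer_top_z = float(outer[:, 2].max())
    flip_params = CrickParams(
        r0=C.SHORT_FLIP_RADIUS, omega0=0.0, omega1=C.IDEAL_TWIST,
        phi0=spec.inner_helix.phi0 + C.SHORT_FLIP_AZIMUTH,
        phi1=C.SHORT_FLIP_PHASE, r1=spec.outer_helix.r1,
        delta_z=C.IDEAL_RISE, orientation="down",
        z_offset=outer_top_z + C.SHORT_FLIP_TOP_Z_OFFSET,
        n_res=spec.flipping_helix_len)
    flipping = generate_helix(flip_params)

    gap = float(np.linalg.norm(flipping[0] - outer[-1]))
    if gap > spec.hinge_len * C.CA_CA_BOND:
        raise ClosureError(
            f"turn hinge endpoints are {gap:.2f} Å apart, beyond "
            f"{spec.hinge_len} x {C.CA_CA_BOND} = {spec.hinge_len * C.CA_CA_BOND:.1f} Å")

    candidates = _turn_candidates(outer, spec.hinge_len)
    base = np.concatenate([inner, outer], axis=0)
    best = None
    for template, hinge_pts, probe in candidates:
        mismatch = float(np.linalg.norm(probe - flipping[0]))
        # reject templates whose CA path collides with the built segments
        dmin = min(float(cdist(hinge_pts, base[:-1]).min()),
                   float(cdist(hinge_pts, flipping[1:]).min()))
        seam = float(np.linalg.norm(hinge_pts[-1] - flipping[0]))
        if dmin < C.CLASH_CA_CA or seam < C.CLASH_CA_CA:
            continue
        if best is None or mismatch < best[0]:
            best = (mismatch, template, hinge_pts)
    if best is None:
        raise ClosureError("no turn template closes the hinge without clashing")
    _, template, hinge = best

    monomer = np.concatenate([inner, outer, hinge, flipping], axis=0)
    torsions = [TorsionTriple(*C.ABEGO_CANONICAL_TORSIONS[letter], C.TRANS_OMEGA)
                for letter in template]
    model = _assemble(spec, monomer, "short", torsions)
    return model


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def measure_height(model: BundleModel) -> float:
    """Axial extent: max z minus min z over all CA atoms (Å)."""
    if not model.chains:
        raise ParameterError("cannot measure the height of an empty model")
    coords = model.all_ca()
    if coords.size == 0:
        raise ParameterError("cannot measure the height of an empty model")
    return float(coords[:, 2].max() - coords[:, 2].min())


def check_ion_site(model: BundleModel, residue_index: int,
                   window: tuple[float, float] = C.ION_WINDOW,
                   proxy_offset: float = C.ION_PROXY_OFFSET) -> IonSiteReport:
    """Check whether three symmetry-related residues frame an ion site.

    A pseudo coordination atom is placed ``proxy_offset`` Å from each CA
    toward the symmetry axis (in the xy plane); the site is feasible iff the
    pseudo atoms' common centroid lies on the axis and every atom falls
    within the coordination-distance window of the centroid.
    """
    lo, hi = window
    atoms = []
    for cid in model.chain_ids:
        ca = model.residue_ca(cid, residue_index)
        r = float(np.hypot(ca[0], ca[1]))
        if proxy_offset > 0 and r > 1e-9:
            scale = (r - proxy_offset) / r  # may overshoot past the axis
            atoms.append(np.array([ca[0] * scale, ca[1] * scale, ca[2]]))
        else:
            atoms.append(ca.copy())
    atoms = np.array(atoms)
    centroid = atoms.mean(axis=0)
    dists = np.linalg.norm(atoms - centroid, axis=1)
    on_axis = float(np.hypot(centroid[0], centroid[1])) <= C.ION_AXIS_TOL
    feasible = bool(on_axis and np.all((dists >= lo) & (dists <= hi)))
    return IonSiteReport(feasible=feasible,
                         triad_radius=float(dists.mean()),
                         centroid_z=float(centroid[2]),
                         coordination_distance_window=(lo, hi))


def mutate_hinge(spec: ArchitectureSpec, new_sequence: str) -> ArchitectureSpec:
    """Replace the hinge window sequence (hinge residues + backup residue).

    ``new_sequence`` has length ``hinge_len + 1``; e.g. GGGT -> GVDQ swaps
    the three hinge residues and the backup residue.  Pure function.
    """
    expected = spec.hinge_len + 1
    if len(new_sequence) != expected:
        raise ParameterError(
            f"hinge window sequence must have length {expected}, "
            f"got {len(new_sequence)}")
    for aa in new_sequence:
        if aa not in AMINO_ACIDS:
            raise ParameterError(f"invalid amino-acid letter {aa!r}")
    return replace(spec, hinge_sequence=new_sequence[:-1],
                   backup_residue=new_sequence[-1])
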