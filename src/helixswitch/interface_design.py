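"""A/X interface-layer enumeration, assignment, burial analysis and scoring.

The interface between the inner helices and the folded-back flipping helices
is organized into three stacked layers, each either a buried hydrogen-bond
network ("A") or a hydrophobic packing layer ("X").  Configurations are
named by a three-letter code ordered hinge-proximal first (XAX, AAA, ...).
Networks are buried in the short state but partially exposed in the long
state, so the number and position of A layers tunes the relative stability
of the two states: hydrophobic-rich interfaces favor the short state, an
all-network interface favors the long state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc

from . import constants as C
from .errors import ParameterError, ResidueLookupError
from .state_builder import BundleModel

__all__ = [
    "LayerConfig",
    "LayerAssignment",
    "enumerate_configs",
    "assign_layers",
    "apply_config",
    "burial_delta",
    "score_state_preference",
    "polar_triad_check",
    "residue_sasa",
]


@dataclass(frozen=True)
class LayerConfig:
    """Three-position layer code over {A, X}, hinge-proximal first."""

    code: str

    def __post_init__(self):
        if len(self.code) != 3 or any(ch not in "AX" for ch in self.code):
            raise ParameterError(
                f"layer code must be 3 characters over {{A, X}}, got {self.code!r}")

    def __str__(self) -> str:
        return self.code

    @classmethod
    def parse(cls, name: str) -> "LayerConfig":
        return cls(name)

    @property
    def n_networks(self) -> int:
        return self.code.count("A")


@dataclass
class LayerAssignment:
    """Residue-index sets per layer, hinge-proximal first.

    ``inner`` and ``flipping`` hold one frozenset of 1-based residue indices
    per layer; ``identities`` records the residue letters assigned by
    :func:`apply_config` (empty until a config is applied).
    """

    inner: list[frozenset]
    flipping: list[frozenset]
    identities: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.inner)


def enumerate_configs(n_positions: int = 3) -> list[LayerConfig]:
    """All 2^k layer permutations, lexicographically sorted.

    With the default three positions this is the full eight-member design
    family (AAA ... XXX).
    """
    codes = sorted("".join(p) for p in itertools.product("AX", repeat=n_positions))
    if n_positions == 3:
        return [LayerConfig(code) for code in codes]
    return codes  # generalized enumeration returns raw codes


def assign_layers(model: BundleModel, n_layers: int = C.N_LAYERS) -> LayerAssignment:
    """Partition the inner/flipping interface into z slabs, hinge-proximal first.

    Contacts are CA pairs within the contact cutoff between the base_inner
    and flipping segments of one monomer (the assignment is C3-symmetric, so
    one chain suffices).  The contact zone is sliced into ``n_layers`` equal
    z slabs ordered by proximity to the hinge; ties go to the lower-index
    (hinge-proximal) layer.  The assignment is computed on the short state
    and reused unchanged for the long state of the same architecture.
    """
    segs = np.array(model.segments)
    inner_idx = np.nonzero(segs == "base_inner")[0]
    flip_idx = np.nonzero(segs == "flipping")[0]
    if inner_idx.size == 0 or flip_idx.size == 0:
        raise ParameterError("model lacks base_inner or flipping segments")
    if flip_idx.size > 1:
        flip_idx = flip_idx[1:]  # first flipping residue belongs to the hinge window
    chain = model.chains[model.chain_ids[0]]
    hinge_idx = np.nonzero(segs == "hinge")[0]
    hinge_z = float(chain[hinge_idx, 2].mean()) if hinge_idx.size else float(chain[:, 2].max())

    d = cdist(chain[inner_idx], chain[flip_idx])
    inner_contact = inner_idx[d.min(axis=1) <= C.LAYER_CONTACT_CUTOFF]
    flip_contact = flip_idx[d.min(axis=0) <= C.LAYER_CONTACT_CUTOFF]
    if inner_contact.size < n_layers or flip_contact.size < n_layers:
        raise ParameterError("fewer than %d contact shells found at the interface"
                             % n_layers)

    zs = chain[np.concatenate([inner_contact, flip_contact]), 2]
    z_lo, z_hi = float(zs.min()), float(zs.max())
    thickness = (z_hi - z_lo) / n_layers or 1.0

    def slab_of(z: float) -> int:
        # layer 0 is nearest the hinge; the hinge sits above the contact zone
        frac = (z_hi - z) / thickness if hinge_z >= z_hi else (z - z_lo) / thickness
        return int(min(n_layers - 1, np.floor(frac - 1e-9) if frac > 0 else 0))

    inner_layers = [set() for _ in range(n_layers)]
    flip_layers = [set() for _ in range(n_layers)]
    for idx in inner_contact:
        inner_layers[slab_of(float(chain[idx, 2]))].add(int(idx) + 1)
    for idx in flip_contact:
        flip_layers[slab_of(float(chain[idx, 2]))].add(int(idx) + 1)
    if any(not s for s in inner_layers) or any(not s for s in flip_layers):
        raise ParameterError("fewer than %d contact shells found at the interface"
                             % n_layers)
    return LayerAssignment(inner=[frozenset(s) for s in inner_layers],
                           flipping=[frozenset(s) for s in flip_layers])


def apply_config(model: BundleModel, assignment: LayerAssignment,
                 config: LayerConfig | str) -> BundleModel:
    """Set layer residue identities on every chain; pure and idempotent.

    A layers place an asparagine network core on the inner side with
    Ser/Thr support on the flipping side; X layers use branched
    hydrophobics graded by layer position.  Non-layer residues are
    untouched.
    """
    config = LayerConfig(str(config))
    if len(config.code) != assignment.n_layers:
        raise ParameterError("config length does not match the layer assignment")
    n = model.n_res
    identities = {}
    new_seq = {}
    for cid, seq in model.sequence.items():
        letters = list(seq)
        for k, kind in enumerate(config.code):
            inner_aa = C.A_LAYER_INNER if kind == "A" else C.X_LAYER_INNER[k]
            flip_aa = C.A_LAYER_FLIP[k] if kind == "A" else C.X_LAYER_FLIP[k]
            for res in assignment.inner[k]:
                if not (1 <= res <= n):
                    raise ResidueLookupError(f"layer residue {res} outside the model")
                letters[res - 1] = inner_aa
            for res in assignment.flipping[k]:
                if not (1 <= res <= n):
                    raise ResidueLookupError(f"layer residue {res} outside the model")
                letters[res - 1] = flip_aa
            identities[k] = {"inner": inner_aa, "flipping": flip_aa}
        new_seq[cid] = "".join(letters)
    out = BundleModel(chains={k: v.copy() for k, v in model.chains.items()},
                      segments=list(model.segments), sequence=new_seq,
                      state_tag=model.state_tag,
                      hinge_torsions=list(model.hinge_torsions))
    assignment.identities = identities
    return out


# ---------------------------------------------------------------------------
# SASA (coarse-grained Shrake-Rupley on CA pseudo-residues)
# ---------------------------------------------------------------------------

def _to_atom_array(model: BundleModel) -> struc.AtomArray:
    coords = model.all_ca()
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    per_chain = model.n_res
    arr.chain_id = np.repeat(np.array(model.chain_ids), per_chain)
    arr.res_id = np.tile(np.arange(1, per_chain + 1), len(model.chain_ids))
    arr.atom_name = np.full(n, "CA")
    arr.res_name = np.full(n, "ALA")
    arr.element = np.full(n, "C")
    return arr


def residue_sasa(model: BundleModel) -> dict[str, np.ndarray]:
    """Per-residue SASA (Å²) for each chain.

    Shrake-Rupley with a 1.4 Å probe on uniform 3.0 Å CA pseudo-residue
    spheres (coarse-grained: one sphere per residue).
    """
    arr = _to_atom_array(model)
    radii = np.full(arr.array_length(), C.SASA_CA_RADIUS)
    sasa = struc.sasa(arr, probe_radius=C.SASA_PROBE_RADIUS,
                      point_number=C.SASA_N_POINTS, vdw_radii=radii)
    per_chain = model.n_res
    return {cid: sasa[i * per_chain:(i + 1) * per_chain]
            for i, cid in enumerate(model.chain_ids)}


def burial_delta(short_model: BundleModel, long_model: BundleModel,
                 assignment: LayerAssignment) -> dict[str, np.ndarray]:
    """Per-layer SASA change on state extension (long minus short, Å²).

    Sums over the layer's residues on all chains, separately for the
    inner-helix side and the flipping-helix side.  Inner-side deltas are
    non-negative: residues covered by the flipping helix in the short state
    become exposed when it leaves.
    """
    if short_model.n_res != long_model.n_res:
        raise ParameterError("models do not share residue indexing")
    n = short_model.n_res
    for layer in list(assignment.inner) + list(assignment.flipping):
        for res in layer:
            if not (1 <= res <= n):
                raise ResidueLookupError(f"layer residue {res} outside the models")
    sasa_s = residue_sasa(short_model)
    sasa_l = residue_sasa(long_model)

    def layer_sum(sasa: dict, residues: frozenset) -> float:
        return float(sum(sasa[cid][res - 1] for cid in sasa for res in residues))

    out = {}
    for side, layers in (("inner", assignment.inner), ("flipping", assignment.flipping)):
        out[side] = np.array([layer_sum(sasa_l, lay) - layer_sum(sasa_s, lay)
                              for lay in layers])
    return out


def score_state_preference(config: LayerConfig | str,
                           burial_deltas: np.ndarray | None = None,
                           weights: tuple | None = None) -> float:
    """Signed state-preference score; negative favors the short state.

    A linear proxy for the fold-and-dock ranking: each hydrogen-bond layer
    contributes a long-favoring term (its network is weaker and partially
    exposed when buried in the short state), each hydrophobic layer a
    short-favoring term, weighted hinge-proximal > distal and scaled by the
    layer's share of the burial change between states.  Weights were
    calibrated once against the observed states (XXA/XAX/XAA short, AAA
    long) and frozen.
    """
    config = LayerConfig(str(config))
    w_a, w_x = weights if weights is not None else (C.SCORE_W_A, C.SCORE_W_X)
    if burial_deltas is not None:
        d = np.asarray(burial_deltas, dtype=float)
        total = d.sum()
        frac = d / total if total > 0 else np.full(len(d), 1.0 / len(d))
    else:
        frac = np.full(3, 1.0 / 3.0)
    score = 0.0
    for k, kind in enumerate(config.code):
        if kind == "A":
            score += w_a[k] * frac[k]
        else:
            score -= w_x[k] * frac[k]
    return float(score)


def polar_triad_check(model: BundleModel, residues,
                      window: tuple[float, float] = C.TRIAD_DISTANCE_WINDOW,
                      proxy_offset: float = C.ION_PROXY_OFFSET) -> tuple[bool, dict]:
    """Geometric stand-in for a cyclic hydrogen-bond network check.

    For each residue, pseudo donor/acceptor points are placed
    ``proxy_offset`` Å from the three symmetry-related CAs toward the axis;
    the residue qualifies iff all three pairwise distances fall inside the
    window (a closed cyclic network).  Returns whether any residue
    qualifies, plus the per-residue pairwise distances.
    """
    lo, hi = window
    report = {}
    ok = False
    for res in sorted(residues):
        pts = []
        for cid in model.chain_ids:
            ca = model.residue_ca(cid, res)
            r = float(np.hypot(ca[0], ca[1]))
            if proxy_offset > 0 and r > 1e-9:
                scale = (r - proxy_offset) / r
                pts.append(np.array([ca[0] * scale, ca[1] * scale, ca[2]]))
            else:
                pts.append(np.asarray(ca, dtype=float))
        pts = np.array(pts)
        dists = (float(np.linalg.norm(pts[0] - pts[1])),
                 float(np.linalg.norm(pts[0] - pts[2])),
                 float(np.linalg.norm(pts[1] - pts[2])))
        qualifies = all(lo <= dd <= hi for dd in dists)
        report[res] = {"distances": dists, "qualifies": qualifies}
        ok = ok or qualifies
    return ok, report
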