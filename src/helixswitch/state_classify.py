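"""Superposition, symmetry-aware RMSD, and short/long/other classification.

Candidate trimer structures (e.g. structure-prediction decoys) are compared
against the designed short and long reference backbones by the minimum
Kabsch RMSD over the three cyclic chain relabelings of the C3 point group;
anti-cyclic mappings are excluded because the chains are oriented (N -> C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as C
from .errors import ParameterError
from .state_builder import BundleModel

__all__ = [
    "ClassificationResult",
    "kabsch_superpose",
    "symmetric_rmsd",
    "classify_state",
    "state_fractions",
]

_CYCLIC_MAPPINGS = (("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B"))


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of comparing one structure to the two reference states."""

    label: str              # short | long | other
    rmsd_short: float
    rmsd_long: float
    chain_mapping_short: tuple[str, ...]
    chain_mapping_long: tuple[str, ...]


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q.

    Returns ``(rotation, translation, rmsd)`` such that ``P @ rotation.T +
    translation`` optimally matches ``Q``.  The rotation is proper
    (determinant +1); reflections are never used.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if len(P) != len(Q):
        raise ParameterError(f"coordinate sets differ in length: {len(P)} vs {len(Q)}")
    if len(P) < 3:
        raise ParameterError("superposition requires at least 3 points")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    if np.linalg.matrix_rank(P0) < 2 or np.linalg.matrix_rank(Q0) < 2:
        raise ParameterError("degenerate (rank-deficient) coordinates")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    t = Qc - Pc @ R.T
    return R, t, rmsd


def _stack(model: BundleModel, order: tuple[str, ...]) -> np.ndarray:
    return np.concatenate([model.chains[c] for c in order], axis=0)


def symmetric_rmsd(model: BundleModel, reference: BundleModel) -> tuple[float, tuple[str, ...]]:
    """Minimum Kabsch RMSD over the three cyclic chain permutations.

    Both models must be three-chain with matching per-chain residue counts.
    Returns the best RMSD and the chain order of ``model`` that was matched
    against the reference's (A, B, C).
    """
    if len(model.chains) != 3 or len(reference.chains) != 3:
        raise ParameterError("symmetric_rmsd requires three-chain models")
    ref = _stack(reference, tuple(reference.chain_ids))
    best_rmsd, best_map = np.inf, None
    ids = tuple(model.chain_ids)
    for shift in range(3):
        order = tuple(ids[(k + shift) % 3] for k in range(3))
        cand = _stack(model, order)
        if len(cand) != len(ref):
            raise ParameterError("models differ in per-chain residue counts")
        _, _, rmsd = kabsch_superpose(cand, ref)
        if rmsd < best_rmsd:
            best_rmsd, best_map = rmsd, order
    return float(best_rmsd), best_map


def classify_state(structure: BundleModel, short_ref: BundleModel,
                   long_ref: BundleModel,
                   threshold: float = C.CLASSIFY_THRESHOLD) -> ClassificationResult:
    """Label a structure short, long, or other.

    The label is the reference with the smaller symmetric RMSD, provided
    that RMSD is within ``threshold`` Å; ties (within 1e-6 Å) and structures
    far from both references are labeled ``other``.
    """
    rmsd_s, map_s = symmetric_rmsd(structure, short_ref)
    rmsd_l, map_l = symmetric_rmsd(structure, long_ref)
    if abs(rmsd_s - rmsd_l) < 1e-6:
        label = "other"
    elif rmsd_s < rmsd_l and rmsd_s <= threshold:
        label = "short"
    elif rmsd_l < rmsd_s and rmsd_l <= threshold:
        label = "long"
    else:
        label = "other"
    return ClassificationResult(label=label, rmsd_short=float(rmsd_s),
                                rmsd_long=float(rmsd_l),
                                chain_mapping_short=map_s,
                                chain_mapping_long=map_l)


def state_fractions(decoys, short_ref: BundleModel, long_ref: BundleModel,
                    threshold: float = C.CLASSIFY_THRESHOLD) -> tuple[float, float, float]:
    """Fractions of a decoy set classified short / long / other (sum to 1)."""
    decoys = list(decoys)
    if not decoys:
        raise ParameterError("state_fractions requires a non-empty decoy list")
    counts = {"short": 0, "long": 0, "other": 0}
    for decoy in decoys:
        counts[classify_state(decoy, short_ref, long_ref, threshold).label] += 1
    n = len(decoys)
    return counts["short"] / n, counts["long"] / n, counts["other"] / n
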