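"""File formats and seeded fixture generation.

PDB (CA traces with chain IDs A/B/C), 3-column whitespace ``.dat`` SAXS
profiles (q, I, sigma), JSON architecture/config files, and CSV
chemical-shift tables.  Every artifact written carries a metadata header
(tool version, seed, config hash) so runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from . import __version__
from . import constants as C
from .errors import FormatError, ParameterError
from .geometry import TorsionTriple
from .solution_obs import ScatteringProfile, debye_profile
from .state_builder import (ArchitectureSpec, BundleModel, build_long_state,
                            build_short_state, default_architecture)

logger = logging.getLogger("helixswitch")

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_profile",
    "write_profile",
    "generate_fixtures",
]

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


def _metadata_remarks(metadata: dict | None) -> list[str]:
    meta = {"version": __version__}
    if metadata:
        meta.update(metadata)
    blob = json.dumps(meta, sort_keys=True)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    lines = [f"REMARK 100 HELIXSWITCH {k}={v}" for k, v in sorted(meta.items())]
    lines.append(f"REMARK 100 HELIXSWITCH config_hash={digest}")
    return lines


def write_pdb(model: BundleModel, path, metadata: dict | None = None) -> None:
    """Write a BundleModel as a CA-only PDB file (fixed-width v3.3 records).

    Chain IDs and 1-based residue numbering are preserved; segment labels
    and the state tag are stored in REMARK records so the package's own
    reader can restore them.
    """
    n_chain = model.n_res
    total = n_chain * len(model.chains)
    arr = struc.AtomArray(total)
    coords = np.concatenate([model.chains[c] for c in model.chain_ids])
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.repeat(np.array(model.chain_ids, dtype="U4"), n_chain)
    arr.res_id = np.tile(np.arange(1, n_chain + 1), len(model.chains))
    arr.atom_name = np.full(total, "CA", dtype="U6")
    res_names = np.concatenate([
        np.array([_ONE_TO_THREE.get(aa, "ALA") for aa in model.sequence[c]])
        for c in model.chain_ids])
    arr.res_name = res_names
    arr.element = np.full(total, "C", dtype="U2")

    pdbf = pdb.PDBFile()
    pdbf.set_structure(arr)
    remarks = _metadata_remarks(metadata)
    remarks.append("REMARK 101 HELIXSWITCH state_tag=" + model.state_tag)
    remarks.append("REMARK 101 HELIXSWITCH segments=" + ",".join(model.segments))
    if model.hinge_torsions:
        tors = ";".join(f"{t.phi:.1f}:{t.psi:.1f}:{t.omega:.1f}"
                        for t in model.hinge_torsions)
        remarks.append("REMARK 101 HELIXSWITCH hinge_torsions=" + tors)
    pdbf.lines = remarks + pdbf.lines
    Path(path).write_text("\n".join(pdbf.lines) + "\n")


def read_pdb(path) -> BundleModel:
    """Read a PDB file into a BundleModel (CA atoms per chain, residue order).

    Duplicate CA records for a residue keep the first occurrence (with a
    warning); models without exactly three chains load but are flagged via a
    warning and ``state_tag='unknown'``.  Raises :class:`FormatError` when
    no ATOM records are present.
    """
    path = Path(path)
    try:
        pdbf = pdb.PDBFile.read(str(path))
        arr = pdbf.get_structure(model=1)
    except Exception as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"no ATOM records in {path}")
    ca = arr[arr.atom_name == "CA"]
    if ca.array_length() == 0:
        raise FormatError(f"no CA atoms in {path}")

    chains: dict[str, list] = {}
    seqs: dict[str, list] = {}
    seen = set()
    for i in range(ca.array_length()):
        cid = str(ca.chain_id[i])
        res = int(ca.res_id[i])
        key = (cid, res)
        if key in seen:
            logger.warning("duplicate CA for %s %d in %s: keeping first", cid, res, path)
            continue
        seen.add(key)
        chains.setdefault(cid, []).append(ca.coord[i])
        seqs.setdefault(cid, []).append(_THREE_TO_ONE.get(str(ca.res_name[i]), "A"))
    chain_arrays = {cid: np.array(pts, dtype=float) for cid, pts in chains.items()}
    if len(chain_arrays) != 3:
        logger.warning("%s has %d chains (expected 3); flagged", path, len(chain_arrays))

    # restore package metadata if present
    state_tag, segments, torsions = "unknown", None, []
    for line in pdbf.lines:
        if line.startswith("REMARK 101 HELIXSWITCH state_tag="):
            state_tag = line.split("=", 1)[1].strip()
        elif line.startswith("REMARK 101 HELIXSWITCH segments="):
            segments = line.split("=", 1)[1].strip().split(",")
        elif line.startswith("REMARK 101 HELIXSWITCH hinge_torsions="):
            for chunk in line.split("=", 1)[1].strip().split(";"):
                phi, psi, omega = (float(v) for v in chunk.split(":"))
                torsions.append(TorsionTriple(phi, psi, omega))
    n = len(next(iter(chain_arrays.values())))
    if segments is None or len(segments) != n:
        segments = ["unknown"] * n
    sequence = {cid: "".join(seqs[cid]) for cid in chain_arrays}
    return BundleModel(chains=chain_arrays, segments=segments, sequence=sequence,
                       state_tag=state_tag, hinge_torsions=torsions)


# ---------------------------------------------------------------------------
# SAXS profiles (3-column whitespace dialect)
# ---------------------------------------------------------------------------

def write_profile(profile: ScatteringProfile, path, metadata: dict | None = None) -> None:
    meta = {"version": __version__}
    if metadata:
        meta.update(metadata)
    lines = [f"# helixswitch {k}={v}" for k, v in sorted(meta.items())]
    lines.append("#      q            I(q)          sigma")
    sigma = profile.effective_sigma()
    for qk, ik, sk in zip(profile.q, profile.I, sigma):
        lines.append(f"{qk:14.6e} {ik:14.6e} {sk:14.6e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> ScatteringProfile:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"bad profile line in {path}: {line!r}")
        rows.append([float(v) for v in parts[:3]])
    if not rows:
        raise FormatError(f"no data rows in {path}")
    data = np.array(rows)
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringProfile(q=data[:, 0], I=data[:, 1], sigma=sigma)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _noised(model: BundleModel, rng: np.random.Generator, scale: float) -> BundleModel:
    return BundleModel(
        chains={c: v + rng.normal(scale=scale, size=v.shape)
                for c, v in model.chains.items()},
        segments=list(model.segments), sequence=dict(model.sequence),
        state_tag="unknown", hinge_torsions=list(model.hinge_torsions))


def generate_fixtures(seed: int, spec: ArchitectureSpec | None = None,
                      outdir="fixtures", n_decoys_per_state: int = 5,
                      decoy_noise: float = 0.5, saxs_noise: float = 0.02) -> dict:
    """Emit a reproducible directory of test inputs.

    Short/long reference PDBs, noised decoys for each state, synthetic SAXS
    profiles for both states with multiplicative Gaussian noise, and a CSV
    of synthetic per-residue chemical-shift differences.  Byte-identical for
    identical seeds.
    """
    spec = spec or default_architecture()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    meta = {"seed": seed}

    short = build_short_state(spec)
    long_ = build_long_state(spec)
    write_pdb(short, out / "short_ref.pdb", metadata=meta)
    write_pdb(long_, out / "long_ref.pdb", metadata=meta)

    files = {"short_ref": out / "short_ref.pdb", "long_ref": out / "long_ref.pdb",
             "decoys": [], "saxs": {}, "shifts": out / "shifts.csv"}
    for label, ref in (("short", short), ("long", long_)):
        for k in range(n_decoys_per_state):
            decoy = _noised(ref, rng, decoy_noise)
            p = out / f"decoy_{label}_{k}.pdb"
            write_pdb(decoy, p, metadata={**meta, "source_state": label,
                                          "noise_A": decoy_noise})
            files["decoys"].append(p)

    for label, ref in (("short", short), ("long", long_)):
        profile = debye_profile(ref.all_ca())
        noisy_I = profile.I * (1.0 + saxs_noise * rng.normal(size=profile.I.shape))
        noisy = ScatteringProfile(q=profile.q, I=noisy_I,
                                  sigma=np.maximum(saxs_noise * np.abs(profile.I),
                                                   C.SIGMA_FLOOR))
        p = out / f"saxs_{label}.dat"
        write_profile(noisy, p, metadata={**meta, "source_state": label,
                                          "noise": saxs_noise})
        files["saxs"][label] = p

    # synthetic chemical-shift differences between the two states: large in
    # the hinge and flipping segments (they move), small in the base
    lines = ["chain,residue,atom_group,delta_H,delta_C,delta_N"]
    segs = short.segments
    for res, seg in enumerate(segs, start=1):
        big = seg in ("hinge", "flipping")
        scale_h = 0.15 if big else 0.02
        dh_me, dc = rng.normal(0, scale_h), rng.normal(0, scale_h * 4)
        dh_am, dn = rng.normal(0, scale_h), rng.normal(0, scale_h * 10)
        lines.append(f"A,{res},methyl,{dh_me:.4f},{dc:.4f},0.0000")
        lines.append(f"A,{res},amide,{dh_am:.4f},0.0000,{dn:.4f}")
    files["shifts"].write_text("\n".join(lines) + "\n")

    logger.info("fixtures written to %s (seed=%d)", out, seed)
    return files
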