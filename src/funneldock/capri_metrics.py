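"""CAPRI-style structural accuracy metrics for docked decoys.

Three measures, all against the bound (native) complex:

* ``Lrmsd`` — C-alpha RMSD of the smaller partner (ligand) after
  superposing the larger partner (receptor) onto the native.
* ``Irmsd`` — heavy-atom RMSD over the native interface residues (any
  inter-partner heavy-atom distance <= 4.0 A) after superposing those same
  residues.
* ``fnat`` — fraction of native inter-partner residue-residue contacts
  (any heavy-atom pair <= 5.0 A) recovered in the decoy.

A decoy is "near-native" when Irmsd <= 4.0 A. Quality classes follow the
Irmsd thresholds used in benchmark assessment: <1.0 high, [1.0, 2.0)
medium, [2.0, 4.0] acceptable, otherwise incorrect.

Interface and contact determination use heavy atoms only, so results do
not depend on hydrogen placement. Residues are matched between native and
decoy by (chain, residue number, insertion code); unmatched residues are
dropped pairwise with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structmodel import ComplexPose, Structure, apply_transform, read_pdb, split_partners, superpose

__all__ = [
    "INTERFACE_CUTOFF",
    "CONTACT_CUTOFF",
    "NEAR_NATIVE_IRMSD",
    "MetricSet",
    "compute_lrmsd",
    "compute_irmsd",
    "compute_fnat",
    "compute_metrics",
    "is_near_native",
    "classify_quality",
    "QUALITY_LABELS",
    "batch_metrics",
]

INTERFACE_CUTOFF = 4.0  # A, inter-partner heavy-atom distance defining interface residues
CONTACT_CUTOFF = 5.0  # A, any-atom-pair distance defining a residue-residue contact
NEAR_NATIVE_IRMSD = 4.0  # A, inclusive

QUALITY_LABELS = ("high", "medium", "acceptable", "incorrect")


@dataclass(frozen=True)
class MetricSet:
    """Bundle of the three accuracy measures for one decoy."""

    lrmsd: float
    irmsd: float
    fnat: float

    def __post_init__(self) -> None:
        if self.lrmsd < 0 or self.irmsd < 0 or not (0.0 <= self.fnat <= 1.0):
            raise ValueError(f"invalid metric values: {self}")


def _common_residues(a: Structure, b: Structure) -> list[tuple]:
    amap, bmap = a.residue_map(), b.residue_map()
    common = [rid for rid in amap if rid in bmap]
    dropped = (set(amap) | set(bmap)) - set(common)
    if dropped:
        warnings.warn(f"{len(dropped)} residue(s) without a match dropped", stacklevel=3)
    return common


def _paired_coords_ca(native: Structure, decoy: Structure) -> tuple[np.ndarray, np.ndarray]:
    nmap, dmap = native.residue_map(), decoy.residue_map()
    npts, dpts = [], []
    missing = 0
    for rid in _common_residues(native, decoy):
        na, da = nmap[rid].atom("CA"), dmap[rid].atom("CA")
        if na is None or da is None:
            missing += 1
            continue
        npts.append(na.xyz)
        dpts.append(da.xyz)
    if missing:
        warnings.warn(f"{missing} shared residue(s) missing CA skipped", stacklevel=3)
    return np.array(npts).reshape(-1, 3), np.array(dpts).reshape(-1, 3)


def compute_lrmsd(native: ComplexPose, decoy: ComplexPose) -> float:
    """Ligand RMSD: superpose decoy receptor C-alphas onto the native
    receptor, then C-alpha RMSD of the ligand without further fitting."""
    rec_n, rec_d = _paired_coords_ca(native.receptor, decoy.receptor)
    if len(rec_n) < 3:
        raise ValueError("fewer than 3 shared receptor CA atoms")
    rot, tran, _ = superpose(rec_d, rec_n)
    lig_n, lig_d = _paired_coords_ca(native.ligand, decoy.ligand)
    if len(lig_n) == 0:
        raise ValueError("no shared ligand residues with CA atoms")
    lig_d = apply_transform(lig_d, rot, tran)
    return float(np.sqrt(np.mean(np.sum((lig_d - lig_n) ** 2, axis=1))))


def interface_residues(pose: ComplexPose, cutoff: float = INTERFACE_CUTOFF) -> tuple[set, set]:
    """Residue ids on each partner with any inter-partner heavy-atom
    distance <= cutoff, determined on the given (native) pose."""
    rec_res = [r for r in pose.receptor if r.heavy_atoms()]
    lig_res = [r for r in pose.ligand if r.heavy_atoms()]
    rec_ids, lig_ids = set(), set()
    lig_coords = [r.heavy_coords() for r in lig_res]
    for rr in rec_res:
        rc = rr.heavy_coords()
        for lr, lc in zip(lig_res, lig_coords):
            if cdist(rc, lc).min() <= cutoff:
                rec_ids.add(rr.res_id)
                lig_ids.add(lr.res_id)
    return rec_ids, lig_ids


def _interface_atom_pairs(native: ComplexPose, decoy: ComplexPose):
    rec_ids, lig_ids = interface_residues(native)
    iface = rec_ids | lig_ids
    if not iface:
        raise ValueError("native complex has an empty interface (malformed native)")
    npts, dpts = [], []
    for nat_part, dec_part in (
        (native.receptor, decoy.receptor),
        (native.ligand, decoy.ligand),
    ):
        nmap, dmap = nat_part.residue_map(), dec_part.residue_map()
        for rid in _common_residues(nat_part, dec_part):
            if rid not in iface:
                continue
            nres, dres = nmap[rid], dmap[rid]
            dnames = {a.name for a in dres.heavy_atoms()}
            for a in nres.heavy_atoms():
                if a.name in dnames:
                    npts.append(a.xyz)
                    dpts.append(dres.atom(a.name).xyz)
    return np.array(npts).reshape(-1, 3), np.array(dpts).reshape(-1, 3)


def compute_irmsd(native: ComplexPose, decoy: ComplexPose) -> float:
    """Interface RMSD: heavy atoms of the native-defined interface residues,
    superposed decoy-onto-native over that same atom set."""
    npts, dpts = _interface_atom_pairs(native, decoy)
    if len(npts) < 3:
        raise ValueError("fewer than 3 shared interface heavy atoms")
    _, _, rms = superpose(dpts, npts)
    return rms


def _contact_pairs(pose: ComplexPose, cutoff: float = CONTACT_CUTOFF) -> set[tuple]:
    pairs = set()
    lig_res = [r for r in pose.ligand if r.heavy_atoms()]
    lig_coords = [r.heavy_coords() for r in lig_res]
    for rr in pose.receptor:
        rc = rr.heavy_coords()
        if len(rc) == 0:
            continue
        for lr, lc in zip(lig_res, lig_coords):
            if cdist(rc, lc).min() <= cutoff:
                pairs.add((rr.res_id, lr.res_id))
    return pairs


def compute_fnat(native: ComplexPose, decoy: ComplexPose) -> float:
    """Fraction of native inter-partner residue contacts present in the decoy."""
    native_contacts = _contact_pairs(native)
    if not native_contacts:
        raise ValueError("native complex has zero inter-partner contacts")
    decoy_contacts = _contact_pairs(decoy)
    return len(native_contacts & decoy_contacts) / len(native_contacts)


def compute_metrics(native: ComplexPose, decoy: ComplexPose) -> MetricSet:
    """All three accuracy measures for one decoy."""
    return MetricSet(
        lrmsd=compute_lrmsd(native, decoy),
        irmsd=compute_irmsd(native, decoy),
        fnat=compute_fnat(native, decoy),
    )


def is_near_native(irmsd: float) -> bool:
    """True iff the decoy is within 4.0 A interface RMSD (inclusive)."""
    if irmsd < 0:
        raise ValueError("irmsd must be non-negative")
    return irmsd <= NEAR_NATIVE_IRMSD


def classify_quality(irmsd: float) -> str:
    """Quality class from interface RMSD: high (<1.0), medium ([1.0, 2.0)),
    acceptable ([2.0, 4.0]), else incorrect."""
    if irmsd < 0:
        raise ValueError("irmsd must be non-negative")
    if irmsd < 1.0:
        return "high"
    if irmsd < 2.0:
        return "medium"
    if irmsd <= 4.0:
        return "acceptable"
    return "incorrect"


def batch_metrics(native_pdb, decoy_paths, partners: str) -> pd.DataFrame:
    """Score many decoy PDB files against one native complex.

    Returns a DataFrame with the score-file column dialect: ``description``,
    ``rms`` (Lrmsd), ``Irms`` (Irmsd), ``Fnat``.
    """
    native = split_partners(read_pdb(native_pdb), partners)
    rows = []
    for p in decoy_paths:
        p = Path(p)
        decoy = split_partners(read_pdb(p), partners)
        m = compute_metrics(native, decoy)
        rows.append({"description": p.stem, "rms": m.lrmsd, "Irms": m.irmsd, "Fnat": m.fnat})
    return pd.DataFrame(rows, columns=["description", "rms", "Irms", "Fnat"])
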