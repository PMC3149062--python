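"""Coordinate data model, PDB I/O, partner partitioning, and superposition.

All coordinates are in Angstroms. Residues keep their author-assigned
numbering (including insertion codes); nothing is renumbered. Hydrogens are
parsed and round-tripped but excluded from every metric computation
downstream, which operate on C-alpha or heavy atoms only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ComplexPose",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "split_partners",
    "superpose",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    """A single atom: name, element, Cartesian position in Angstroms."""

    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetatm: bool = False
    serial: int = 0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: xyz must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One residue: identity is (chain_id, resseq, icode); holds >=1 atom."""

    chain_id: str
    resseq: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def res_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.heavy_atoms()], dtype=float)


@dataclass
class Structure:
    """An ordered list of residues; iteration order equals file order."""

    residues: list[Residue] = field(default_factory=list)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def subset_by_chains(self, chain_ids) -> "Structure":
        wanted = set(chain_ids)
        return Structure([r for r in self.residues if r.chain_id in wanted])

    def residue_map(self) -> dict[tuple[str, int, str], Residue]:
        return {r.res_id: r for r in self.residues}

    def coords(self, atom_name: str | None = None, heavy_only: bool = False) -> np.ndarray:
        pts = []
        for res in self.residues:
            for a in res.atoms:
                if atom_name is not None and a.name != atom_name:
                    continue
                if heavy_only and not a.is_heavy:
                    continue
                pts.append(a.xyz)
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass
class ComplexPose:
    """Two docking partners. The receptor is the larger partner by residue
    count; ties go to the first-listed partner in the spec string."""

    receptor: Structure
    ligand: Structure
    partner_spec: str

    def __post_init__(self) -> None:
        rc = set(self.receptor.chains)
        lc = set(self.ligand.chains)
        if rc & lc:
            raise ValueError(f"receptor/ligand chains overlap: {sorted(rc & lc)}")
        if len(self.receptor) < len(self.ligand):
            raise ValueError("receptor must be the larger partner")


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed {what} field {text!r}") from exc


def read_pdb(path, include_hetatm: bool = False) -> Structure:
    """Parse ATOM (and optionally HETATM) records from a PDB file.

    Only the first encountered alternate-location conformer of each atom is
    kept. Occupancy and B-factor are preserved for round-tripping. Parsing
    stops at the first ENDMDL so multi-model files yield model 1.
    """
    residues: list[Residue] = []
    index: dict[tuple[str, int, str], Residue] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                break
            is_het = rec == "HETATM"
            if rec != "ATOM  " and not is_het:
                continue
            if is_het and not include_hetatm:
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            name = line[12:16].strip()
            altloc = line[16]
            resname = line[17:20].strip()
            chain_id = line[21]
            try:
                resseq = int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(
                    f"line {lineno}: malformed residue number {line[22:26]!r}"
                ) from exc
            icode = line[26].strip()
            xyz = np.array(
                [
                    _parse_float(line[30:38], "x", lineno),
                    _parse_float(line[38:46], "y", lineno),
                    _parse_float(line[46:54], "z", lineno),
                ]
            )
            occ = _parse_float(line[54:60], "occupancy", lineno) if line[54:60].strip() else 1.0
            bfac = _parse_float(line[60:66], "B-factor", lineno) if line[60:66].strip() else 0.0
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                # element column absent: infer from the atom name, skipping
                # any leading digit (e.g. "1HB" -> H)
                stripped = name.lstrip("0123456789")
                element = stripped[:1]
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = 0

            key = (chain_id, resseq, icode)
            res = index.get(key)
            if res is None:
                res = Residue(chain_id, resseq, icode, resname)
                index[key] = res
                residues.append(res)
            if altloc not in (" ", "A") and res.atom(name) is not None:
                continue  # keep first-encountered conformer
            if res.atom(name) is not None:
                continue
            res.atoms.append(
                Atom(name, element, xyz, occupancy=occ, bfactor=bfac,
                     is_hetatm=is_het, serial=serial)
            )
    if not residues:
        raise PDBParseError(f"{path}: no ATOM records found")
    return Structure(residues)


def _format_atom_name(name: str, element: str) -> str:
    # Single-letter elements start in column 14 per the PDB convention.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path) -> None:
    """Write ATOM/HETATM records with TER between chains and a final END."""
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for res in structure.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for a in res.atoms:
            serial += 1
            rec = "HETATM" if a.is_hetatm else "ATOM  "
            lines.append(
                f"{rec}{serial:>5d} {_format_atom_name(a.name, a.element)} "
                f"{res.resname:>3s} {res.chain_id}{res.resseq:>4d}{res.icode or ' '}   "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Partner partitioning


def split_partners(structure: Structure, partner_spec: str) -> ComplexPose:
    """Split a structure into receptor and ligand by a "<chains1>_<chains2>"
    partner string (e.g. "A_B", "HL_A"). The larger partner by residue count
    becomes the receptor; on a tie the first-listed partner wins."""
    parts = partner_spec.split("_")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"partner spec {partner_spec!r} must be '<chains1>_<chains2>'")
    chains1, chains2 = list(parts[0]), list(parts[1])
    if set(chains1) & set(chains2):
        raise ValueError(
            f"chain(s) {sorted(set(chains1) & set(chains2))} appear in both partners"
        )
    available = structure.chains
    missing = [c for c in chains1 + chains2 if c not in available]
    if missing:
        raise ValueError(
            f"unknown chain(s) {missing}; available chains: {available}"
        )
    s1 = structure.subset_by_chains(chains1)
    s2 = structure.subset_by_chains(chains2)
    if len(s1) >= len(s2):
        receptor, ligand = s1, s2
    else:
        receptor, ligand = s2, s1
    return ComplexPose(receptor=receptor, ligand=ligand, partner_spec=partner_spec)


# ---------------------------------------------------------------------------
# Least-squares superposition


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation + translation`` attains the minimized RMSD. The
    rotation is guaranteed proper (determinant +1; reflections corrected).

    Parameters
    ----------
    mobile, target : (n, 3) arrays with n >= 3, equal counts, not collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must have shape (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    sup = SVDSuperimposer()
    sup.set(target, mobile)
    sup.run()
    rot, tran = sup.get_rotran()
    rms = float(sup.get_rms())
    if not math.isfinite(rms):
        raise ValueError("degenerate point set: superposition failed")
    return rot, tran, rms


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a superposition transform in the ``superpose`` convention."""
    return np.asarray(coords, dtype=float) @ rotation + translation
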