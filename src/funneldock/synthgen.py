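"""Synthetic complexes and decoy sets with controlled statistical structure.

Two generators make every other module testable without any external data:

* :func:`make_decoy_set` draws decoy score/accuracy records from a
  two-population mixture — a "near-native" population with interface RMSD
  in [0.3, 4.0] A appearing with probability ``near_native_fraction`` and
  a "far" population in (4.0, 20.0] A — with interface energy following a
  linear-plus-plateau funnel,
  ``i_sc = funnel_slope * (10 - min(irmsd, 10)) + noise``:
  a negative slope deepens the energy of near-native decoys (a funnel),
  zero slope decouples score from accuracy, and a positive slope inverts
  the funnel. This is the simplest shape that reproduces the
  success/failure scatter seen in real energy-vs-RMSD plots; it makes no
  claim to model real energetics.
* :func:`make_toy_complex` builds small two-partner coordinate models
  (idealized helix pairs, beta-hairpin pairs, or random coils) with a
  requested number of native inter-partner contacts and no steric clash,
  plus "unbound" variants whose backbone and side chains are perturbed by
  stated amounts to emulate rigid-body versus backbone-change difficulty.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .capri_metrics import NEAR_NATIVE_IRMSD
from .decoy_eval import DecoyRecord, DecoySet
from .docking_engine import CentroidScoreWeights, DockingSystem, RigidBodyPose, score_centroid
from .structmodel import Atom, ComplexPose, Residue, Structure

__all__ = [
    "DecoySetSpec",
    "ToyComplexSpec",
    "make_decoy_set",
    "make_toy_complex",
    "make_unbound_variant",
    "make_failure_fixture",
    "near_native_count",
]


@dataclass
class DecoySetSpec:
    """Statistical recipe for a synthetic decoy set."""

    n_decoys: int = 1000
    near_native_fraction: float = 0.1
    funnel_slope: float = -2.0  # score units per A; negative = funnel
    score_noise_sd: float = 1.0
    irmsd_near: tuple[float, float] = (0.3, 4.0)
    irmsd_far: tuple[float, float] = (4.0, 20.0)  # lower bound exclusive
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_decoys < 5:
            raise ValueError("n_decoys must be >= 5")
        if not 0.0 <= self.near_native_fraction <= 1.0:
            raise ValueError("near_native_fraction must be in [0, 1]")
        if self.near_native_fraction > 0 and self.irmsd_near[0] >= self.irmsd_near[1]:
            raise ValueError("empty near range with near_native_fraction > 0")
        if self.irmsd_near[1] > NEAR_NATIVE_IRMSD or self.irmsd_far[0] < NEAR_NATIVE_IRMSD:
            raise ValueError("ranges must be disjoint at the 4.0 A near-native boundary")


def make_decoy_set(spec: DecoySetSpec, provenance: str = "standard",
                   target_id: str = "synthetic") -> DecoySet:
    """Draw a decoy set from the spec's funnel mixture model."""
    rng = np.random.default_rng(spec.seed)
    near = rng.random(spec.n_decoys) < spec.near_native_fraction
    lo_n, hi_n = spec.irmsd_near
    lo_f, hi_f = spec.irmsd_far
    irmsd = np.where(
        near,
        rng.uniform(lo_n, hi_n, spec.n_decoys),
        hi_f - rng.uniform(0.0, hi_f - lo_f, spec.n_decoys),  # (lo_f, hi_f]
    )
    noise = rng.normal(0.0, spec.score_noise_sd, spec.n_decoys)
    i_sc = spec.funnel_slope * (10.0 - np.minimum(irmsd, 10.0)) + noise
    records = [
        DecoyRecord(description=f"decoy_{i:04d}", i_sc=float(i_sc[i]),
                    irmsd=float(irmsd[i]), total_score=float(i_sc[i]))
        for i in range(spec.n_decoys)
    ]
    return DecoySet(records, provenance=provenance, target_id=target_id)


def near_native_count(ds: DecoySet) -> int:
    """Realized number of near-native decoys in a set."""
    return sum(1 for r in ds.records if r.irmsd <= NEAR_NATIVE_IRMSD)


# ---------------------------------------------------------------------------
# Toy coordinate models

_SEQ_CYCLE = ("ALA", "LEU", "GLU", "LYS", "VAL", "SER", "GLY", "ILE", "THR", "ASP")

# Idealized alpha-helix backbone: radius (A), phase offset (deg), z offset (A)
# relative to the CA trace (rise 1.5 A, twist 100 deg per residue).
_HELIX_GEOM = {"N": (1.5, -28.0, -0.9), "CA": (2.3, 0.0, 0.0),
               "C": (1.7, 26.0, 0.9), "O": (2.0, 40.0, 1.4)}


@dataclass
class ToyComplexSpec:
    """Recipe for a small synthetic two-partner complex."""

    n_residues: int = 20  # per partner
    geometry: str = "two-helix"  # or "beta-hairpin-pair", "random-coil"
    contact_count: int = 12  # target native contact count (+-2)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("two-helix", "beta-hairpin-pair", "random-coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues per partner")


def _make_residue(chain: str, resseq: int, resname: str, backbone: dict[str, np.ndarray],
                  cb: np.ndarray | None) -> Residue:
    atoms = [Atom(name, name[0], xyz) for name, xyz in backbone.items()]
    if resname != "GLY" and cb is not None:
        atoms.append(Atom("CB", "C", cb))
    return Residue(chain, resseq, "", resname, atoms)


def _helix_chain(chain: str, n: int, phase0: float = 0.0, mirror: bool = False) -> Structure:
    """Ideal helix along z; CB pseudo-side-chains point radially outward.
    ``mirror`` flips x so a translated copy faces the original, and
    ``phase0`` rotates the side chains so the two helices interdigitate."""
    residues = []
    sx = -1.0 if mirror else 1.0
    for i in range(n):
        phi = np.radians(100.0 * i + phase0)
        z = 1.5 * i
        backbone = {}
        for name, (r, dphi, dz) in _HELIX_GEOM.items():
            a = phi + np.radians(dphi)
            backbone[name] = np.array([sx * r * np.cos(a), r * np.sin(a), z + dz])
        cb = np.array([sx * 3.3 * np.cos(phi), 3.3 * np.sin(phi), z])
        resname = _SEQ_CYCLE[i % len(_SEQ_CYCLE)]
        residues.append(_make_residue(chain, i + 1, resname, backbone, cb))
    return Structure(residues)


def _strand_chain(chain: str, n: int) -> Structure:
    """Beta-hairpin: two antiparallel extended strands joined by a turn."""
    residues = []
    half = n // 2
    for i in range(n):
        if i < half:
            x, y = 3.4 * i, 0.0
        else:
            x, y = 3.4 * (n - 1 - i), 4.8
        zig = 1.0 if i % 2 == 0 else -1.0
        backbone = {
            "N": np.array([x - 1.2, y, 0.4 * zig]),
            "CA": np.array([x, y, 0.6 * zig]),
            "C": np.array([x + 1.2, y, 0.4 * zig]),
            "O": np.array([x + 1.3, y + 1.0, 0.4 * zig]),
        }
        cb = np.array([x, y - 1.0 if i < half else y + 1.0, 1.8 * zig])
        residues.append(_make_residue(chain, i + 1, _SEQ_CYCLE[i % len(_SEQ_CYCLE)], backbone, cb))
    return Structure(residues)


def _coil_chain(chain: str, n: int, rng: np.random.Generator) -> Structure:
    """Random walk of CA positions with fixed 3.8 A steps, mild self-avoidance."""
    cas = [np.zeros(3)]
    while len(cas) < n:
        step = rng.normal(size=3)
        step = 3.8 * step / np.linalg.norm(step)
        cand = cas[-1] + step
        if len(cas) < 2 or min(np.linalg.norm(cand - c) for c in cas[:-1]) > 3.0:
            cas.append(cand)
    residues = []
    for i, ca in enumerate(cas):
        backbone = {
            "N": ca + np.array([-1.2, 0.3, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.3, 0.0]),
            "O": ca + np.array([1.4, 1.4, 0.0]),
        }
        cb = ca + np.array([0.0, -1.2, 1.0])
        residues.append(_make_residue(chain, i + 1, _SEQ_CYCLE[i % len(_SEQ_CYCLE)], backbone, cb))
    return Structure(residues)


def _translate(s: Structure, vec: np.ndarray) -> Structure:
    s = copy.deepcopy(s)
    for res in s:
        for a in res.atoms:
            a.xyz = a.xyz + vec
    return s


def _native_contact_count(pose: ComplexPose) -> int:
    from .capri_metrics import _contact_pairs  # internal reuse

    return len(_contact_pairs(pose))


def make_toy_complex(spec: ToyComplexSpec) -> ComplexPose:
    """Build a clash-free bound complex with roughly the requested number
    of native inter-partner contacts (within +-2 where geometrically
    feasible; the closest achievable separation otherwise)."""
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "two-helix":
        a = _helix_chain("A", spec.n_residues)
        b = _helix_chain("B", spec.n_residues, phase0=180.0, mirror=True)
        axis = np.array([1.0, 0.0, 0.0])
    elif spec.geometry == "beta-hairpin-pair":
        a = _strand_chain("A", spec.n_residues)
        b = _strand_chain("B", spec.n_residues)
        axis = np.array([0.0, 1.0, 0.0])
    else:
        a = _coil_chain("A", spec.n_residues, rng)
        b = _coil_chain("B", spec.n_residues, rng)
        axis = np.array([1.0, 0.0, 0.0])

    best: tuple[int, ComplexPose] | None = None
    for sep in np.arange(16.0, 5.0, -0.1):
        pose = ComplexPose(receptor=a, ligand=_translate(b, sep * axis), partner_spec="A_B")
        system = DockingSystem(pose)
        bd = score_centroid(system, RigidBodyPose.identity(), CentroidScoreWeights())
        if bd.vdw_term > 0:
            break  # partners have started to clash; stop approaching
        cnt = _native_contact_count(pose)
        if best is None or abs(cnt - spec.contact_count) < abs(best[0] - spec.contact_count):
            best = (cnt, pose)
        if abs(cnt - spec.contact_count) <= 2 and cnt >= spec.contact_count:
            break
    if best is None:
        raise ValueError(f"geometry {spec.geometry!r} infeasible: partners clash at all separations")
    return best[1]


def make_unbound_variant(pose: ComplexPose, backbone_sd: float = 0.0,
                         sidechain_sd: float = 0.5, seed: int | None = None) -> ComplexPose:
    """Emulate unbound conformers superposed on the bound complex by adding
    Gaussian noise to backbone (N/CA/C/O) and side-chain atom positions.
    ``backbone_sd`` = 0 reproduces the bound backbone exactly (rigid-body
    difficulty); larger values emulate binding-induced backbone change."""
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(pose)
    for part in (out.receptor, out.ligand):
        for res in part:
            for a in res.atoms:
                sd = backbone_sd if a.name in ("N", "CA", "C", "O", "OXT") else sidechain_sd
                if sd > 0:
                    a.xyz = a.xyz + rng.normal(0.0, sd, size=3)
    return out


# ---------------------------------------------------------------------------
# Deterministic failure-mode fixtures


def make_failure_fixture(label: str, seed: int = 0,
                         n_decoys: int = 200) -> tuple[DecoySet, DecoySet, DecoySet]:
    """Three linked decoy sets (standard, unbound-refine, bound-refine)
    constructed so the failure classifier recovers ``label``.

    The standard set always fails the funnel criterion with its overall
    minimum energy on a non-near-native decoy; the refinement sets place
    their near-native minima at offsets that fire exactly one cascade rule.
    """
    rng = np.random.default_rng(seed)

    def _set(e_min_far: float, e_min_near: float | None, provenance: str) -> DecoySet:
        records = []
        for i in range(n_decoys):
            irmsd = float(rng.uniform(6.0, 20.0))
            i_sc = float(rng.uniform(e_min_far + 2.0, e_min_far + 10.0))
            records.append(DecoyRecord(f"{provenance}_{i:04d}", i_sc=i_sc, irmsd=irmsd))
        # pin the far minimum exactly
        records[0] = DecoyRecord(f"{provenance}_far_min", i_sc=e_min_far,
                                 irmsd=float(rng.uniform(6.0, 20.0)))
        if e_min_near is not None:
            records[1] = DecoyRecord(f"{provenance}_near_min", i_sc=e_min_near,
                                     irmsd=float(rng.uniform(0.5, 3.5)))
        return DecoySet(records, provenance=provenance, target_id=f"synthetic-{label}")

    # standard run: minimum -10, no near-native decoy anywhere near the top
    std = _set(-10.0, None, "standard")
    if label == "RB sampling":
        ub = _set(-8.0, -15.0, "unbound_refine")
        bd = _set(-8.0, -20.0, "bound_refine")
    elif label == "BB sampling":
        ub = _set(-8.0, -9.0, "unbound_refine")
        bd = _set(-8.0, -20.0, "bound_refine")
    elif label == "discrimination":
        ub = _set(-8.0, -9.5, "unbound_refine")
        bd = _set(-8.0, -9.8, "bound_refine")
    else:
        raise ValueError(f"unknown failure label {label!r}")
    return std, ub, bd
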