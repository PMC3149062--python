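"""Simplified two-stage Monte-Carlo rigid-body docking.

The protocol mirrors the classic multi-scale docking scheme: starting from
a user-supplied pose, (1) a random local perturbation of the ligand
partner, (2) a 500-step Metropolis Monte-Carlo search in a coarse-grained
*centroid* representation (side chains collapsed to one pseudo-atom per
residue) with step sizes adapted toward a 25% acceptance rate, and (3) 50
cycles of all-atom rigid-body refinement in which each random move is
followed by derivative-free minimization of the six rigid-body degrees of
freedom — skipped when the move already raised the score by more than +15
— and a Metropolis test. The receptor stays fixed throughout; all moves
act on the ligand.

The low-resolution score is a weighted sum of four inter-chain terms
(contact 2.0, clash 1.0, environment 1.0, pair 1.0 by default). The
functional forms here are deliberately simple, documented stand-ins — a
capped contact count, a quadratic soft-clash penalty, and pluggable
environment/pair lookup tables defaulting to a hydrophobicity-derived
potential. They are NOT the Rosetta score terms, whose definitions live
outside this package's scope; users can supply their own tables and
all-atom score function.

Side-chain packing steps are interface-parity no-op hooks: this engine
does rigid-body docking only.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .capri_metrics import compute_metrics
from .decoy_eval import DecoyRecord, DecoySet
from .structmodel import BACKBONE_NAMES, ComplexPose, Structure

__all__ = [
    "RigidBodyPose",
    "CentroidModel",
    "CentroidScoreWeights",
    "CentroidScoreBreakdown",
    "MCSchedule",
    "ScoreTables",
    "default_tables",
    "neutral_tables",
    "to_centroid",
    "DockingSystem",
    "score_centroid",
    "local_perturb",
    "run_lowres",
    "run_hires",
    "interface_energy",
    "dock",
    "default_allatom_score",
]

# Per-element soft radii (A); the centroid pseudo-atom gets its own entry.
ATOM_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "CEN": 1.8}
DEFAULT_RADIUS = 1.7

CONTACT_DIST = 6.0  # A, centroid-centroid distance counted as a contact
ENV_PAIR_DIST = 8.0  # A, neighbourhood for the env burial count and pair term
BURIAL_NEIGHBORS = 3  # cross-partner centroid neighbours that flag "buried"
CONTACT_CAP = 5  # max contacts credited to any single residue

# Kyte-Doolittle hydropathy; basis for the default env/pair stand-in tables.
_KD = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


@dataclass(frozen=True)
class RigidBodyPose:
    """Rigid transform applied to the ligand about its reference centroid:
    ``x' = R (x - pivot) + pivot + t``. Composition of moves multiplies
    rotations on the left and adds translations."""

    rotation: np.ndarray
    translation: np.ndarray

    @classmethod
    def identity(cls) -> "RigidBodyPose":
        return cls(np.eye(3), np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be a proper 3x3 matrix (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def moved(self, d_rotation: np.ndarray | None = None,
              d_translation: np.ndarray | None = None) -> "RigidBodyPose":
        """Compose an incremental move applied about the *current* ligand
        centre: R' = dR R, t' = t + dt."""
        R = self.rotation if d_rotation is None else np.asarray(d_rotation) @ self.rotation
        t = self.translation if d_translation is None else self.translation + np.asarray(d_translation)
        return RigidBodyPose(R, t)

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - pivot) @ self.rotation.T + pivot + self.translation


@dataclass
class CentroidModel:
    """Coarse-grained partner: backbone heavy atoms plus one side-chain
    centroid pseudo-atom per residue (glycine's centroid sits on CA)."""

    atom_coords: np.ndarray  # (m, 3) backbone heavies + centroids
    atom_radii: np.ndarray  # (m,)
    centroids: np.ndarray  # (n_res, 3) one per residue
    resnames: list[str]


def to_centroid(structure: Structure) -> CentroidModel:
    """Collapse side chains to per-residue centroid pseudo-atoms.

    The centroid is the geometric mean of the side-chain heavy atoms;
    glycine (or any residue with no side-chain heavies) uses CA. Residues
    missing any of the backbone atoms N, CA, C are skipped with a warning.
    """
    coords, radii, cens, names = [], [], [], []
    skipped = 0
    for res in structure:
        backbone = {a.name: a for a in res.atoms if a.name in BACKBONE_NAMES and a.is_heavy}
        if not {"N", "CA", "C"} <= set(backbone):
            skipped += 1
            continue
        side = [a.xyz for a in res.heavy_atoms() if a.name not in BACKBONE_NAMES]
        cen = np.mean(side, axis=0) if side else backbone["CA"].xyz
        for a in backbone.values():
            coords.append(a.xyz)
            radii.append(ATOM_RADII.get(a.element.upper(), DEFAULT_RADIUS))
        coords.append(cen)
        radii.append(ATOM_RADII["CEN"])
        cens.append(cen)
        names.append(res.resname)
    if skipped:
        warnings.warn(f"{skipped} residue(s) missing backbone atoms skipped", stacklevel=2)
    if not names:
        raise ValueError("no residues with complete backbones")
    return CentroidModel(
        atom_coords=np.array(coords, dtype=float),
        atom_radii=np.array(radii, dtype=float),
        centroids=np.array(cens, dtype=float),
        resnames=names,
    )


@dataclass(frozen=True)
class CentroidScoreWeights:
    """Weights of the four low-resolution score terms."""

    contact: float = 2.0
    vdw: float = 1.0
    env: float = 1.0
    pair: float = 1.0


@dataclass(frozen=True)
class CentroidScoreBreakdown:
    contact_term: float
    vdw_term: float
    env_term: float
    pair_term: float
    weights: CentroidScoreWeights

    @property
    def total(self) -> float:
        w = self.weights
        return (w.contact * self.contact_term + w.vdw * self.vdw_term
                + w.env * self.env_term + w.pair * self.pair_term)


@dataclass(frozen=True)
class ScoreTables:
    """Pluggable residue-environment and residue-pair potentials."""

    env: Callable[[str, bool], float]  # (resname, buried) -> score
    pair: Callable[[str, str], float]  # (resname_a, resname_b) -> score


def _kd(resname: str) -> float:
    try:
        return _KD[resname]
    except KeyError:
        raise ValueError(f"no score-table entry for residue type {resname!r}") from None


def default_tables() -> ScoreTables:
    """Hydrophobicity-derived stand-in: buried hydrophobics are favourable,
    exposed hydrophobics at the interface carry a small penalty, and
    hydrophobic-hydrophobic cross-partner pairs are favoured."""
    return ScoreTables(
        env=lambda res, buried: (-0.1 if buried else 0.02) * _kd(res),
        pair=lambda a, b: -0.02 * _kd(a) * _kd(b),
    )


def neutral_tables() -> ScoreTables:
    """All-zero env/pair tables (accept any residue type)."""
    return ScoreTables(env=lambda res, buried: 0.0, pair=lambda a, b: 0.0)


@dataclass
class MCSchedule:
    """Monte-Carlo schedule; defaults follow the benchmark protocol
    (500-step coarse search adapted to 25% acceptance, 3 A / 8 deg initial
    perturbation with spin, 50 refinement cycles of 0.1 A / 3 deg moves,
    minimization skipped above a +15 score jump)."""

    lowres_cycles: int = 500
    target_acceptance: float = 0.25
    init_translation_sd: float = 3.0  # A
    init_rotation_sd: float = 8.0  # degrees
    hires_cycles: int = 50
    hires_translation_sd: float = 0.1  # A
    hires_rotation_sd: float = 3.0  # degrees
    min_skip_threshold: float = 15.0  # score units
    pack_period: int = 8  # interface parity only; packing is a no-op hook
    kT: float = 0.8  # Metropolis temperature, score units
    adapt_window: int = 50  # steps between step-size adaptations
    adapt_up: float = 1.1  # gentle growth when accepting too often
    adapt_down: float = 0.6  # strong shrink: must recover from the 3 A start within 500 steps
    spin: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("lowres_cycles", "target_acceptance", "hires_cycles",
                     "min_skip_threshold", "pack_period", "kT", "adapt_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"schedule field {name} must be positive")


class DockingSystem:
    """Scorable two-partner system: fixed receptor, movable ligand, in
    both centroid and all-atom representations. Poses are applied about
    the ligand's heavy-atom centroid in the reference frame."""

    def __init__(self, pose: ComplexPose):
        self.complex = pose
        self.receptor_cen = to_centroid(pose.receptor)
        self.ligand_cen = to_centroid(pose.ligand)
        self.rec_atoms = pose.receptor.coords(heavy_only=True)
        self.lig_atoms = pose.ligand.coords(heavy_only=True)
        self.rec_radii = self._radii(pose.receptor)
        self.lig_radii = self._radii(pose.ligand)
        self.rec_sc_cen, self.rec_sc_names = self._sidechain_centroids(pose.receptor)
        self.lig_sc_cen, self.lig_sc_names = self._sidechain_centroids(pose.ligand)
        self.pivot = self.lig_atoms.mean(axis=0)
        self.receptor_com = self.rec_atoms.mean(axis=0)

    @staticmethod
    def _radii(s: Structure) -> np.ndarray:
        return np.array([
            ATOM_RADII.get(a.element.upper(), DEFAULT_RADIUS)
            for res in s for a in res.atoms if a.is_heavy
        ])

    @staticmethod
    def _sidechain_centroids(s: Structure):
        cens, names = [], []
        for res in s:
            heavies = res.heavy_atoms()
            if not heavies:
                continue
            side = [a.xyz for a in heavies if a.name not in BACKBONE_NAMES]
            if side:
                cens.append(np.mean(side, axis=0))
            else:
                ca = res.atom("CA")
                cens.append(ca.xyz if ca is not None else heavies[0].xyz)
            names.append(res.resname)
        return np.array(cens, dtype=float).reshape(-1, 3), names

    def ligand_center(self, pose: RigidBodyPose) -> np.ndarray:
        return self.pivot + pose.translation

    def transformed_ligand_structure(self, pose: RigidBodyPose) -> Structure:
        """Materialize the posed ligand as a Structure (all atoms moved)."""
        lig = copy.deepcopy(self.complex.ligand)
        for res in lig:
            for a in res.atoms:
                a.xyz = pose.apply(a.xyz, self.pivot)
        return lig

    def posed_complex(self, pose: RigidBodyPose) -> ComplexPose:
        return ComplexPose(
            receptor=copy.deepcopy(self.complex.receptor),
            ligand=self.transformed_ligand_structure(pose),
            partner_spec=self.complex.partner_spec,
        )


# ---------------------------------------------------------------------------
# Low-resolution score


def score_centroid(system: DockingSystem, pose: RigidBodyPose,
                   weights: CentroidScoreWeights = CentroidScoreWeights(),
                   tables: ScoreTables | None = None,
                   contact_cap: int = CONTACT_CAP) -> CentroidScoreBreakdown:
    """Four-term inter-chain centroid score.

    contact: -(number of cross-partner residue pairs with centroid distance
    <= 6.0 A, credited at most ``contact_cap`` times per residue on either
    side). vdw: quadratic soft-clash penalty sum((r_min - d)^2 / r_min)
    over overlapping cross-partner atom pairs (backbone heavies and
    centroid pseudo-atoms). env: per interface residue (>= 1 cross-partner
    centroid within 8.0 A), looked up by residue type and buried state
    (>= 3 such neighbours). pair: table lookup over cross-partner residue
    pairs with centroid distance <= 8.0 A.
    """
    if tables is None:
        tables = default_tables()
    rec, lig = system.receptor_cen, system.ligand_cen
    lig_cen = pose.apply(lig.centroids, system.pivot)
    lig_atoms = pose.apply(lig.atom_coords, system.pivot)

    dcen = cdist(rec.centroids, lig_cen)
    contacts = dcen <= CONTACT_DIST
    row = np.minimum(contacts.sum(axis=1), contact_cap)
    col = np.minimum(contacts.sum(axis=0), contact_cap)
    contact_term = -0.5 * float(row.sum() + col.sum())

    d = cdist(rec.atom_coords, lig_atoms)
    rmin = rec.atom_radii[:, None] + lig.atom_radii[None, :]
    overlap = np.maximum(0.0, rmin - d)
    vdw_term = float((overlap**2 / rmin).sum())

    near = dcen <= ENV_PAIR_DIST
    env_term = 0.0
    rec_nb, lig_nb = near.sum(axis=1), near.sum(axis=0)
    for names, counts in ((rec.resnames, rec_nb), (lig.resnames, lig_nb)):
        for name, c in zip(names, counts):
            if c >= 1:
                env_term += tables.env(name, bool(c >= BURIAL_NEIGHBORS))

    pair_term = 0.0
    for i, j in zip(*np.nonzero(near)):
        pair_term += tables.pair(rec.resnames[i], lig.resnames[j])

    return CentroidScoreBreakdown(contact_term, vdw_term, env_term, pair_term, weights)


# ---------------------------------------------------------------------------
# All-atom score (default; pluggable)


def default_allatom_score(system: DockingSystem, pose: RigidBodyPose,
                          tables: ScoreTables | None = None,
                          eps: float = 0.05, cap: float = 10.0) -> float:
    """Soft 6-12 potential over cross-partner heavy atoms plus the pair
    table over side-chain centroids. A documented stand-in, not the
    all-atom potential of any production package."""
    if tables is None:
        tables = default_tables()
    lig_atoms = pose.apply(system.lig_atoms, system.pivot)
    d = cdist(system.rec_atoms, lig_atoms)
    sigma = system.rec_radii[:, None] + system.lig_radii[None, :]
    near = d <= 2.5 * sigma
    x = sigma[near] / np.maximum(d[near], 0.5)
    lj = eps * (x**12 - 2.0 * x**6)
    total = float(np.minimum(lj, cap).sum())

    lig_sc = pose.apply(system.lig_sc_cen, system.pivot)
    dsc = cdist(system.rec_sc_cen, lig_sc)
    for i, j in zip(*np.nonzero(dsc <= ENV_PAIR_DIST)):
        total += tables.pair(system.rec_sc_names[i], system.lig_sc_names[j])
    return total


# ---------------------------------------------------------------------------
# Moves


def _random_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _gaussian_rotation(rng: np.random.Generator, sd_degrees: float) -> np.ndarray:
    axis = _random_axis(rng)
    angle = np.radians(rng.normal(0.0, sd_degrees))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def local_perturb(pose: RigidBodyPose, system: DockingSystem,
                  schedule: MCSchedule, rng: np.random.Generator) -> RigidBodyPose:
    """Random starting perturbation: Gaussian translation (sd per axis),
    Gaussian rotation about a random axis, and — when ``schedule.spin`` —
    a uniform spin of the ligand about the receptor-to-ligand
    centre-of-mass axis. RNG draws occur in that order."""
    dt = rng.normal(0.0, schedule.init_translation_sd, size=3)
    dR = _gaussian_rotation(rng, schedule.init_rotation_sd)
    new = pose.moved(d_rotation=dR, d_translation=dt)
    if schedule.spin:
        axis = system.ligand_center(new) - system.receptor_com
        n = np.linalg.norm(axis)
        axis = axis / n if n > 0 else np.array([0.0, 0.0, 1.0])
        spin = Rotation.from_rotvec(rng.uniform(0.0, 2.0 * np.pi) * axis).as_matrix()
        new = new.moved(d_rotation=spin)
    return new


def _metropolis(delta: float, kT: float, rng: np.random.Generator) -> bool:
    return delta <= 0 or rng.random() < np.exp(-delta / kT)


# ---------------------------------------------------------------------------
# Low-resolution Monte Carlo


def run_lowres(system: DockingSystem, pose: RigidBodyPose, schedule: MCSchedule,
               rng: np.random.Generator,
               weights: CentroidScoreWeights = CentroidScoreWeights(),
               tables: ScoreTables | None = None,
               score_fn: Callable | None = None) -> tuple[RigidBodyPose, dict]:
    """Adaptive Metropolis search in the centroid representation.

    Every ``adapt_window`` steps the translation/rotation magnitudes are
    scaled up (x1.1) when the window acceptance exceeded the target and
    down (x0.9) when it fell short. Returns the lowest-scoring pose
    visited and trajectory statistics.
    """
    if tables is None:
        tables = default_tables()
    if score_fn is None:
        score_fn = lambda sys_, p: score_centroid(sys_, p, weights, tables).total  # noqa: E731
    score = score_fn(system, pose)
    best_pose, best_score = pose, score
    trans_mag = schedule.init_translation_sd
    rot_mag = schedule.init_rotation_sd
    accepted_window = 0
    accepted_total = 0
    history: list[float] = []
    for step in range(1, schedule.lowres_cycles + 1):
        dt = rng.normal(0.0, trans_mag, size=3)
        dR = _gaussian_rotation(rng, rot_mag)
        trial = pose.moved(d_rotation=dR, d_translation=dt)
        trial_score = score_fn(system, trial)
        if _metropolis(trial_score - score, schedule.kT, rng):
            pose, score = trial, trial_score
            accepted_window += 1
            accepted_total += 1
            if score < best_score:
                best_pose, best_score = pose, score
        if step % schedule.adapt_window == 0:
            rate = accepted_window / schedule.adapt_window
            history.append(rate)
            if rate > schedule.target_acceptance:
                trans_mag *= schedule.adapt_up
                rot_mag *= schedule.adapt_up
            elif rate < schedule.target_acceptance:
                trans_mag *= schedule.adapt_down
                rot_mag *= schedule.adapt_down
            accepted_window = 0
    stats = {
        "best_score": best_score,
        "accept_rate": accepted_total / schedule.lowres_cycles,
        "acceptance_history": history,
        "final_translation_mag": trans_mag,
        "final_rotation_mag": rot_mag,
    }
    return best_pose, stats


# ---------------------------------------------------------------------------
# High-resolution refinement


def _minimize_rigid_body(system: DockingSystem, pose: RigidBodyPose,
                         score_fn, score: float,
                         trans_step: float = 0.2, rot_step_deg: float = 2.0,
                         tol: float = 1e-3, max_sweeps: int = 5):
    """Derivative-free coordinate descent over the six rigid-body DOF with
    shrinking steps; stops when a full sweep improves the score by less
    than ``tol`` or the step sizes bottom out."""
    axes = np.eye(3)
    for _ in range(max_sweeps):
        start = score
        for kind in ("t", "r"):
            for i in range(3):
                for sign in (1.0, -1.0):
                    if kind == "t":
                        trial = pose.moved(d_translation=sign * trans_step * axes[i])
                    else:
                        dR = Rotation.from_rotvec(
                            np.radians(sign * rot_step_deg) * axes[i]).as_matrix()
                        trial = pose.moved(d_rotation=dR)
                    s = score_fn(system, trial)
                    if s < score - 1e-12:
                        pose, score = trial, s
                        break
        if start - score < tol:
            trans_step *= 0.5
            rot_step_deg *= 0.5
            if trans_step < 0.01:
                break
    return pose, score


def run_hires(system: DockingSystem, pose: RigidBodyPose, schedule: MCSchedule,
              rng: np.random.Generator, score_fn=None,
              pack_hook: Callable[[int], None] | None = None) -> tuple[RigidBodyPose, dict]:
    """All-atom rigid-body refinement: 50 cycles of {small Gaussian move;
    rigid-body minimization unless the move raised the score by more than
    +15; Metropolis test}. ``pack_hook`` is called every ``pack_period``
    cycles in lieu of side-chain packing (a no-op by default)."""
    if score_fn is None:
        score_fn = default_allatom_score
    score = score_fn(system, pose)
    best_pose, best_score = pose, score
    n_min_skipped = 0
    n_packs = 0
    accepted = 0
    for cycle in range(1, schedule.hires_cycles + 1):
        dt = rng.normal(0.0, schedule.hires_translation_sd, size=3)
        dR = _gaussian_rotation(rng, schedule.hires_rotation_sd)
        trial = pose.moved(d_rotation=dR, d_translation=dt)
        trial_score = score_fn(system, trial)
        if trial_score - score <= schedule.min_skip_threshold:
            trial, trial_score = _minimize_rigid_body(system, trial, score_fn, trial_score)
        else:
            n_min_skipped += 1
        if cycle % schedule.pack_period == 0:
            n_packs += 1
            if pack_hook is not None:
                pack_hook(cycle)
        if _metropolis(trial_score - score, schedule.kT, rng):
            pose, score = trial, trial_score
            accepted += 1
            if score < best_score:
                best_pose, best_score = pose, score
    stats = {
        "best_score": best_score,
        "accept_rate": accepted / schedule.hires_cycles,
        "n_min_skipped": n_min_skipped,
        "n_pack_calls": n_packs,
    }
    return best_pose, stats


# ---------------------------------------------------------------------------
# Interface energy and the full pipeline


def interface_energy(system: DockingSystem, pose: RigidBodyPose, score_fn=None) -> float:
    """Score of the pose minus the score with the ligand translated 500 A
    away along the receptor-to-ligand axis (the separated reference)."""
    if score_fn is None:
        score_fn = default_allatom_score
    axis = system.ligand_center(pose) - system.receptor_com
    n = np.linalg.norm(axis)
    axis = axis / n if n > 0 else np.array([0.0, 0.0, 1.0])
    separated = pose.moved(d_translation=500.0 * axis)
    return score_fn(system, pose) - score_fn(system, separated)


def dock(start: ComplexPose, n_decoys: int, schedule: MCSchedule | None = None,
         rng: np.random.Generator | int | None = None,
         weights: CentroidScoreWeights = CentroidScoreWeights(),
         tables: ScoreTables | None = None, score_fn=None,
         native: ComplexPose | None = None, refine_only: bool = False,
         target_id: str = "", description_prefix: str = "decoy",
         provenance: str | None = None) -> DecoySet:
    """Generate a decoy set by repeated perturb / coarse-search / refine
    runs from the starting pose.

    ``native`` (default: the starting pose itself) is the reference for
    the accuracy metrics recorded per decoy. ``refine_only`` skips the
    initial perturbation and the centroid stage, mirroring a local
    refinement run. Deterministic for a fixed integer seed / generator.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    schedule = schedule or MCSchedule()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(schedule.seed if rng is None else rng)
    system = DockingSystem(start)
    reference = native if native is not None else start
    records = []
    for i in range(n_decoys):
        pose = RigidBodyPose.identity()
        if not refine_only:
            pose = local_perturb(pose, system, schedule, rng)
            pose, _ = run_lowres(system, pose, schedule, rng, weights, tables)
        pose, _ = run_hires(system, pose, schedule, rng, score_fn)
        total = (score_fn or default_allatom_score)(system, pose)
        i_sc = interface_energy(system, pose, score_fn)
        decoy = system.posed_complex(pose)
        m = compute_metrics(reference, decoy)
        records.append(DecoyRecord(
            description=f"{description_prefix}_{i:04d}",
            i_sc=i_sc, irmsd=m.irmsd, total_score=total,
            lrmsd=m.lrmsd, fnat=m.fnat,
        ))
    if provenance is None:
        provenance = "unbound_refine" if refine_only else "standard"
    return DecoySet(records, provenance=provenance, target_id=target_id)
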