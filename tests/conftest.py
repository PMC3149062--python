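import numpy as np
import pytest

from funneldock.structmodel import Atom, ComplexPose, Residue, Structure
from funneldock.synthgen import ToyComplexSpec, make_toy_complex


def make_structure(chain_residues):
    """Build a Structure from {chain: [(resname, {atom: xyz}), ...]}."""
    residues = []
    for chain, res_list in chain_residues.items():
        for i, (resname, atoms) in enumerate(res_list, start=1):
            residues.append(Residue(chain, i, "", resname, [
                Atom(name, name[0], np.asarray(xyz, dtype=float))
                for name, xyz in atoms.items()
            ]))
    return Structure(residues)


def simple_residue(resname="ALA", origin=(0.0, 0.0, 0.0)):
    """Backbone + CB at fixed offsets from an origin."""
    o = np.asarray(origin, dtype=float)
    atoms = {
        "N": o + [-1.2, 0.3, 0.0],
        "CA": o,
        "C": o + [1.2, 0.3, 0.0],
        "O": o + [1.4, 1.4, 0.0],
    }
    if resname != "GLY":
        atoms["CB"] = o + [0.0, -1.2, 1.0]
    return (resname, atoms)


def two_chain_pose(gap=4.5, n_per_chain=4, spacing=6.0):
    """Two parallel rows of residues facing each other across ``gap`` in y
    (measured between the closest atoms, the CB tips at y=-1.2 / y=+1.2
    offsets). Gap refers to CA-row separation."""
    a_rows = [simple_residue("ALA", (spacing * i, 0.0, 0.0)) for i in range(n_per_chain)]
    b_rows = []
    for i in range(n_per_chain):
        o = np.array([spacing * i, -gap, 0.0])
        atoms = {
            "N": o + [-1.2, -0.3, 0.0],
            "CA": o,
            "C": o + [1.2, -0.3, 0.0],
            "O": o + [1.4, -1.4, 0.0],
            "CB": o + [0.0, 1.2, 1.0],  # points back toward chain A
        }
        b_rows.append(("LEU", atoms))
    s = make_structure({"A": a_rows + [simple_residue("GLY", (0.0, 8.0, 8.0))],
                        "B": b_rows})
    from funneldock.structmodel import split_partners

    return split_partners(s, "A_B")


@pytest.fixture(scope="session")
def helix_pose() -> ComplexPose:
    """Clash-free two-helix toy complex with ~12 native contacts."""
    return make_toy_complex(ToyComplexSpec(geometry="two-helix", n_residues=16,
                                           contact_count=12, seed=1))


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng)).as_matrix()


def rigid_transform_pose(pose: ComplexPose, R: np.ndarray, t: np.ndarray) -> ComplexPose:
    """Apply one global rigid transform to every atom of both partners."""
    import copy

    out = copy.deepcopy(pose)
    for part in (out.receptor, out.ligand):
        for res in part:
            for a in res.atoms:
                a.xyz = R @ a.xyz + t
    return out
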