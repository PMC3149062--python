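"""Docking engine: centroid conversion, score terms against brute-force
oracles, move generation, adaptive Monte Carlo, refinement rules, and
pipeline determinism."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_structure
from funneldock.docking_engine import (
    ATOM_RADII,
    BURIAL_NEIGHBORS,
    CONTACT_DIST,
    ENV_PAIR_DIST,
    CentroidScoreWeights,
    DockingSystem,
    MCSchedule,
    RigidBodyPose,
    default_tables,
    dock,
    interface_energy,
    local_perturb,
    neutral_tables,
    run_hires,
    run_lowres,
    score_centroid,
    to_centroid,
)
from funneldock.structmodel import ComplexPose


class TestToCentroid:
    def test_alanine_centroid_is_cb(self):
        s = make_structure({"A": [("ALA", {
            "N": (0, 1.3, 0), "CA": (0, 0, 0), "C": (1.3, 0, 0), "O": (2.0, 1.0, 0),
            "CB": (-0.8, -1.0, 0.9)})]})
        cm = to_centroid(s)
        np.testing.assert_allclose(cm.centroids[0], [-0.8, -1.0, 0.9])

    def test_glycine_centroid_is_ca(self):
        s = make_structure({"A": [("GLY", {
            "N": (0, 1.3, 0), "CA": (0.5, 0, 0.2), "C": (1.3, 0, 0)})]})
        cm = to_centroid(s)
        np.testing.assert_allclose(cm.centroids[0], [0.5, 0, 0.2])

    def test_leucine_centroid_is_sidechain_mean(self):
        side = {"CB": (1.0, 0, 0), "CG": (2.0, 0.5, 0), "CD1": (3.0, 0, 1.0),
                "CD2": (3.0, 1.0, -1.0)}
        s = make_structure({"A": [("LEU", {
            "N": (0, 1.3, 0), "CA": (0, 0, 0), "C": (-1.3, 0, 0), **side})]})
        cm = to_centroid(s)
        np.testing.assert_allclose(cm.centroids[0],
                                   np.mean(list(side.values()), axis=0))

    def test_missing_backbone_skipped_with_warning(self):
        s = make_structure({"A": [
            ("ALA", {"N": (0, 1.3, 0), "CA": (0, 0, 0), "C": (1.3, 0, 0), "CB": (0, -1, 1)}),
            ("ALA", {"CA": (5, 0, 0), "CB": (5, -1, 1)}),  # no N/C
        ]})
        with pytest.warns(UserWarning, match="backbone"):
            cm = to_centroid(s)
        assert len(cm.centroids) == 1


def single_contact_pose():
    """Two one-residue partners: centroids ~4.6 A apart (one contact), no
    atom pair inside clash distance."""
    a = make_structure({"A": [("ALA", {
        "N": (-1.2, 0.3, 0), "CA": (0, 0, 0), "C": (1.2, 0.3, 0),
        "O": (1.4, 1.4, 0), "CB": (0, -1.2, 1.0)})]})
    b = make_structure({"B": [("ALA", {
        "N": (-1.2, -7.3, 0), "CA": (0, -7.0, 0), "C": (1.2, -7.3, 0),
        "O": (1.4, -8.4, 0), "CB": (0, -5.8, 1.0)})]})
    from funneldock.structmodel import Structure

    return ComplexPose(receptor=a, ligand=b, partner_spec="A_B")


class TestScoreCentroid:
    def test_separated_partners_score_zero(self, helix_pose):
        system = DockingSystem(helix_pose)
        far = RigidBodyPose.identity().moved(d_translation=np.array([100.0, 0, 0]))
        bd = score_centroid(system, far)
        assert (bd.contact_term, bd.vdw_term, bd.env_term, bd.pair_term) == (0, 0, 0, 0)
        assert bd.total == 0.0

    def test_single_contact_with_neutral_tables(self):
        system = DockingSystem(single_contact_pose())
        bd = score_centroid(system, RigidBodyPose.identity(), tables=neutral_tables())
        assert bd.contact_term == -1.0
        assert bd.vdw_term == 0.0
        assert bd.total == pytest.approx(-2.0)  # contact weight 2.0

    def test_total_is_exact_weighted_sum(self, helix_pose):
        system = DockingSystem(helix_pose)
        w = CentroidScoreWeights(contact=2.0, vdw=1.5, env=0.5, pair=3.0)
        bd = score_centroid(system, RigidBodyPose.identity(), weights=w)
        assert bd.total == (2.0 * bd.contact_term + 1.5 * bd.vdw_term
                            + 0.5 * bd.env_term + 3.0 * bd.pair_term)

    def test_terms_match_plain_loop_oracle(self, helix_pose):
        """Recompute every term with unvectorized loops over the same
        centroid model."""
        system = DockingSystem(helix_pose)
        pose = RigidBodyPose.identity().moved(d_translation=np.array([0.5, -0.4, 0.3]))
        bd = score_centroid(system, pose)
        tables = default_tables()
        rec, lig = system.receptor_cen, system.ligand_cen
        lig_cen = pose.apply(lig.centroids, system.pivot)
        lig_atoms = pose.apply(lig.atom_coords, system.pivot)

        nr, nl = len(rec.centroids), len(lig_cen)
        pairs = [(i, j) for i in range(nr) for j in range(nl)
                 if np.linalg.norm(rec.centroids[i] - lig_cen[j]) <= CONTACT_DIST]
        row = [min(sum(1 for i2, _ in pairs if i2 == i), 5) for i in range(nr)]
        col = [min(sum(1 for _, j2 in pairs if j2 == j), 5) for j in range(nl)]
        contact = -0.5 * (sum(row) + sum(col))

        vdw = 0.0
        for i, (xa, ra) in enumerate(zip(rec.atom_coords, rec.atom_radii)):
            for xb, rb in zip(lig_atoms, lig.atom_radii):
                d = np.linalg.norm(xa - xb)
                if d < ra + rb:
                    vdw += (ra + rb - d) ** 2 / (ra + rb)

        env = 0.0
        for k, name in enumerate(rec.resnames):
            c = sum(1 for j in range(nl)
                    if np.linalg.norm(rec.centroids[k] - lig_cen[j]) <= ENV_PAIR_DIST)
            if c >= 1:
                env += tables.env(name, c >= BURIAL_NEIGHBORS)
        for k, name in enumerate(lig.resnames):
            c = sum(1 for i in range(nr)
                    if np.linalg.norm(rec.centroids[i] - lig_cen[k]) <= ENV_PAIR_DIST)
            if c >= 1:
                env += tables.env(name, c >= BURIAL_NEIGHBORS)

        pair = sum(tables.pair(rec.resnames[i], lig.resnames[j])
                   for i in range(nr) for j in range(nl)
                   if np.linalg.norm(rec.centroids[i] - lig_cen[j]) <= ENV_PAIR_DIST)

        assert bd.contact_term == pytest.approx(contact)
        assert bd.vdw_term == pytest.approx(vdw)
        assert bd.env_term == pytest.approx(env)
        assert bd.pair_term == pytest.approx(pair)

    def test_invariant_under_global_rigid_transform(self, helix_pose):
        """Moving the whole complex rigidly cannot change any score term."""
        from conftest import rigid_transform_pose

        system = DockingSystem(helix_pose)
        base = score_centroid(system, RigidBodyPose.identity())
        R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        moved = rigid_transform_pose(helix_pose, R, np.array([5.0, -3.0, 11.0]))
        bd = score_centroid(DockingSystem(moved), RigidBodyPose.identity())
        assert bd.total == pytest.approx(base.total, abs=1e-8)
        assert bd.vdw_term >= 0.0

    def test_unknown_residue_type_named_in_error(self):
        pose = single_contact_pose()
        pose.ligand.residues[0].resname = "XXX"
        system = DockingSystem(pose)
        with pytest.raises(ValueError, match="XXX"):
            score_centroid(system, RigidBodyPose.identity())


class TestLocalPerturb:
    def test_zero_sd_leaves_position_unchanged_except_spin(self, helix_pose):
        system = DockingSystem(helix_pose)
        sched = MCSchedule(init_translation_sd=1e-12, init_rotation_sd=1e-12, spin=True)
        rng = np.random.default_rng(0)
        p = local_perturb(RigidBodyPose.identity(), system, sched, rng)
        np.testing.assert_allclose(p.translation, 0.0, atol=1e-9)
        # spin is a rotation about the COM axis: ligand centre preserved
        np.testing.assert_allclose(system.ligand_center(p), system.pivot, atol=1e-9)
        assert not np.allclose(p.rotation, np.eye(3))  # the spin did rotate

    def test_deterministic_under_fixed_seed(self, helix_pose):
        system = DockingSystem(helix_pose)
        sched = MCSchedule()
        a = local_perturb(RigidBodyPose.identity(), system, sched, np.random.default_rng(5))
        b = local_perturb(RigidBodyPose.identity(), system, sched, np.random.default_rng(5))
        np.testing.assert_array_equal(a.rotation, b.rotation)
        np.testing.assert_array_equal(a.translation, b.translation)

    def test_translation_sd_matches_schedule(self, helix_pose):
        system = DockingSystem(helix_pose)
        sched = MCSchedule(spin=False)
        rng = np.random.default_rng(17)
        draws = np.array([
            local_perturb(RigidBodyPose.identity(), system, sched, rng).translation
            for _ in range(10_000)
        ])
        for axis_sd in draws.std(axis=0, ddof=1):
            assert axis_sd == pytest.approx(3.0, rel=0.05)


class TestRunLowres:
    def test_flat_score_accepts_everything_and_grows_steps(self, helix_pose):
        """With the partners far apart and zero tables the landscape is
        flat: Metropolis accepts every move and adaptation grows the
        steps."""
        system = DockingSystem(helix_pose)
        start = RigidBodyPose.identity().moved(d_translation=np.array([500.0, 0, 0]))
        sched = MCSchedule(lowres_cycles=200)
        _, stats = run_lowres(system, start, sched, np.random.default_rng(0),
                              tables=neutral_tables())
        assert stats["accept_rate"] > 0.99
        assert stats["final_translation_mag"] > sched.init_translation_sd

    def test_quadratic_funnel_reaches_basin(self, helix_pose):
        """Analytic toy score with a single minimum at a 2 A offset: the
        search must end below its starting score and near the basin."""
        system = DockingSystem(helix_pose)
        target = np.array([2.0, 0.0, 0.0])

        def quad(sys_, pose):
            return float(np.sum((pose.translation - target) ** 2))

        start = RigidBodyPose.identity().moved(d_translation=np.array([8.0, -5.0, 3.0]))
        best, stats = run_lowres(system, start, MCSchedule(), np.random.default_rng(2),
                                 score_fn=quad)
        assert stats["best_score"] <= quad(system, start)
        assert quad(system, best) < 1.0  # inside the basin

    def test_adaptive_controller_lands_in_acceptance_band(self, helix_pose):
        """After adaptation the tail acceptance rate sits near the 25%
        target: mean over seeds within [0.15, 0.35]."""
        system = DockingSystem(helix_pose)
        tails = []
        for seed in range(6):
            sched = MCSchedule(spin=False)
            rng = np.random.default_rng(seed)
            _, stats = run_lowres(system, RigidBodyPose.identity(), sched, rng)
            tails.append(np.mean(stats["acceptance_history"][-4:]))
        assert 0.15 <= np.mean(tails) <= 0.35

    def test_best_pose_not_worse_than_any_accepted(self, helix_pose):
        system = DockingSystem(helix_pose)
        sched = MCSchedule(lowres_cycles=100, spin=False)
        rng = np.random.default_rng(9)
        p = local_perturb(RigidBodyPose.identity(), system, sched, rng)
        start_score = score_centroid(system, p).total
        best, stats = run_lowres(system, p, sched, rng)
        assert stats["best_score"] <= start_score
        assert score_centroid(system, best).total == pytest.approx(stats["best_score"])


class TestRunHires:
    def test_stationary_at_quadratic_minimum(self, helix_pose):
        system = DockingSystem(helix_pose)

        def quad(sys_, pose):
            ang = np.linalg.norm(Rotation.from_matrix(pose.rotation).as_rotvec())
            return float(np.sum(pose.translation**2)) + 10.0 * ang**2

        best, stats = run_hires(system, RigidBodyPose.identity(),
                                MCSchedule(), np.random.default_rng(1), score_fn=quad)
        assert stats["best_score"] <= 1e-9 + quad(system, RigidBodyPose.identity())
        assert np.linalg.norm(best.translation) < 0.2

    def test_minimization_skipped_above_threshold(self, helix_pose):
        """A score surface where every move costs +20 (> +15) must skip
        minimization on all 50 cycles."""
        system = DockingSystem(helix_pose)

        def cliff(sys_, pose):
            return 0.0 if np.linalg.norm(pose.translation) < 1e-12 else 20.0

        calls = []
        _, stats = run_hires(system, RigidBodyPose.identity(), MCSchedule(),
                             np.random.default_rng(0), score_fn=cliff,
                             pack_hook=calls.append)
        assert stats["n_min_skipped"] == 50
        assert stats["n_pack_calls"] == 50 // 8
        assert calls == [8, 16, 24, 32, 40, 48]

    def test_refinement_improves_interface_energy(self, helix_pose):
        system = DockingSystem(helix_pose)
        rng = np.random.default_rng(4)
        start = RigidBodyPose.identity().moved(
            d_translation=np.array([0.8, -0.6, 0.4]))
        before = interface_energy(system, start)
        best, _ = run_hires(system, start, MCSchedule(), rng)
        after = interface_energy(system, best)
        assert after <= before + 1e-9


class TestInterfaceEnergy:
    def test_non_interacting_pose_is_zero(self, helix_pose):
        system = DockingSystem(helix_pose)
        far = RigidBodyPose.identity().moved(d_translation=np.array([0.0, 300.0, 0.0]))
        assert interface_energy(system, far) == pytest.approx(0.0, abs=1e-9)

    def test_single_contact_worth_its_score(self):
        system = DockingSystem(single_contact_pose())

        def cen_score(sys_, pose):
            return score_centroid(sys_, pose, tables=neutral_tables()).total

        assert interface_energy(system, RigidBodyPose.identity(),
                                score_fn=cen_score) == pytest.approx(-2.0)

    def test_matches_two_evaluation_oracle(self, helix_pose):
        from funneldock.docking_engine import default_allatom_score

        system = DockingSystem(helix_pose)
        pose = RigidBodyPose.identity().moved(d_translation=np.array([0.3, 0.2, -0.1]))
        bound = default_allatom_score(system, pose)
        axis = (system.ligand_center(pose) - system.receptor_com)
        axis /= np.linalg.norm(axis)
        sep = pose.moved(d_translation=500.0 * axis)
        unbound = default_allatom_score(system, sep)
        assert interface_energy(system, pose) == pytest.approx(bound - unbound)


class TestDockPipeline:
    def test_bit_reproducible_under_fixed_seed(self, helix_pose):
        a = dock(helix_pose, 2, rng=3)
        b = dock(helix_pose, 2, rng=3)
        for r1, r2 in zip(a.records, b.records):
            assert (r1.description, r1.i_sc, r1.irmsd, r1.total_score, r1.lrmsd, r1.fnat) \
                == (r2.description, r2.i_sc, r2.irmsd, r2.total_score, r2.lrmsd, r2.fnat)

    def test_local_docking_recovers_near_native_decoys(self, helix_pose):
        """Easy rigid target, local perturbation: at least one of the
        decoys must come back near-native (irmsd <= 4 A)."""
        ds = dock(helix_pose, 8, schedule=MCSchedule(spin=False), rng=1)
        assert min(r.irmsd for r in ds.records) <= 4.0

    def test_refine_only_stays_closer_than_full_perturbation(self, helix_pose):
        full = dock(helix_pose, 5, schedule=MCSchedule(spin=True), rng=2)
        refined = dock(helix_pose, 5, rng=2, refine_only=True)
        assert np.mean([r.irmsd for r in refined.records]) < \
            np.mean([r.irmsd for r in full.records])
        assert refined.provenance == "unbound_refine"

    def test_invalid_decoy_count_rejected(self, helix_pose):
        with pytest.raises(ValueError, match="n_decoys"):
            dock(helix_pose, 0)
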