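import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wetbind import mm
from wetbind.model_io import AtomRecord, Dihedral, ParameterizedSystem, Trajectory


def _two_atoms(q1, q2, r, eps=0.0, rmh=0.0):
    atoms = [
        AtomRecord(serial=0, name="A", element="X", residue_name="AAA",
                   residue_index=1, mm_charge=q1, lj_epsilon=eps, lj_rmin_half=rmh),
        AtomRecord(serial=1, name="B", element="X", residue_name="BBB",
                   residue_index=2, mm_charge=q2, lj_epsilon=eps, lj_rmin_half=rmh),
    ]
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    return ParameterizedSystem(atoms=atoms, coordinates=coords)


class TestPairwiseNonbonded:
    def test_coulomb_constant(self):
        system = _two_atoms(1.0, -1.0, 3.320637)
        e = mm.pairwise_nonbonded(system, [0], [1], system.coordinates,
                                  dielectric=2.0)
        assert e.elec == pytest.approx(-50.0, abs=1e-9)

    def test_lj_minimum(self):
        system = _two_atoms(0.0, 0.0, 3.8, eps=0.1, rmh=1.9)
        e = mm.pairwise_nonbonded(system, [0], [1], system.coordinates)
        assert e.vdw == pytest.approx(-0.1, abs=1e-12)

    def test_matches_brute_force(self, toy_complex):
        system, bound, _ = toy_complex
        rec = system.selections["receptor"]
        lig = system.selections["ligand"]
        frame = bound.coordinates[0]
        e = mm.pairwise_nonbonded(system, rec, lig, frame, dielectric=2.0)
        q = system.mm_charges()
        eps, rmh = system.lj_params()
        elec = vdw = 0.0
        for i in rec:
            for j in lig:
                r = np.linalg.norm(frame[i] - frame[j])
                elec += mm.COULOMB_K * q[i] * q[j] / (2.0 * r)
                em = np.sqrt(eps[i] * eps[j])
                rm = rmh[i] + rmh[j]
                vdw += em * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        assert e.elec == pytest.approx(elec, abs=1e-8)
        assert e.vdw == pytest.approx(vdw, abs=1e-8)

    def test_symmetry_and_union_decomposition(self, toy_complex):
        system, bound, _ = toy_complex
        rec = system.selections["receptor"]
        lig = system.selections["ligand"]
        frame = bound.coordinates[0]
        ab = mm.pairwise_nonbonded(system, rec, lig, frame)
        ba = mm.pairwise_nonbonded(system, lig, rec, frame)
        # symmetric up to floating-point summation order
        assert ab.elec == pytest.approx(ba.elec, rel=1e-12)
        assert ab.vdw == pytest.approx(ba.vdw, rel=1e-12)
        half = lig[: lig.size // 2]
        rest = lig[lig.size // 2:]
        e1 = mm.pairwise_nonbonded(system, half, rec, frame)
        e2 = mm.pairwise_nonbonded(system, rest, rec, frame)
        assert ab.total == pytest.approx(e1.total + e2.total, abs=1e-10)

    def test_overlapping_groups_rejected(self, toy_complex):
        system, bound, _ = toy_complex
        with pytest.raises(ValueError, match="overlap"):
            mm.pairwise_nonbonded(system, [0, 1], [1, 2], bound.coordinates[0])

    def test_near_singularity_names_atoms(self):
        system = _two_atoms(1.0, 1.0, 1e-6)
        with pytest.raises(mm.NearSingularityError, match="atoms 0 and 1"):
            mm.pairwise_nonbonded(system, [0], [1], system.coordinates)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shift=st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_translation_invariance(self, toy_complex, shift):
        system, bound, _ = toy_complex
        rec = system.selections["receptor"]
        lig = system.selections["ligand"]
        frame = bound.coordinates[0]
        e0 = mm.pairwise_nonbonded(system, rec, lig, frame)
        e1 = mm.pairwise_nonbonded(system, rec, lig, frame + np.asarray(shift))
        assert e1.total == pytest.approx(e0.total, abs=1e-9)

    def test_rotation_invariance(self, toy_complex):
        system, bound, _ = toy_complex
        rec = system.selections["receptor"]
        lig = system.selections["ligand"]
        frame = bound.coordinates[0]
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        e0 = mm.pairwise_nonbonded(system, rec, lig, frame)
        e1 = mm.pairwise_nonbonded(system, rec, lig, frame @ rot.T)
        assert e1.total == pytest.approx(e0.total, abs=1e-9)

    def test_elec_linear_in_inverse_dielectric(self, toy_complex):
        system, bound, _ = toy_complex
        rec = system.selections["receptor"]
        lig = system.selections["ligand"]
        frame = bound.coordinates[0]
        e1 = mm.pairwise_nonbonded(system, rec, lig, frame, dielectric=1.0)
        e2 = mm.pairwise_nonbonded(system, rec, lig, frame, dielectric=2.0)
        assert e2.elec == pytest.approx(e1.elec / 2.0, abs=1e-10)
        assert e2.vdw == pytest.approx(e1.vdw, abs=1e-12)


class TestTorsion:
    @pytest.mark.parametrize(
        "k,n,delta,phi_deg,expected",
        [
            (1.0, 1, 0.0, 180.0, 0.0),
            (1.0, 1, 0.0, 0.0, 2.0),
            # 0.5*(1 + cos(3*60 - 0)) = 0.5*(1 + cos 180) = 0
            (0.5, 3, 0.0, 60.0, 0.0),
        ],
    )
    def test_against_direct_formula(self, k, n, delta, phi_deg, expected):
        phi = np.radians(phi_deg)
        coords = np.array([
            [1.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0],
            [np.cos(phi), np.sin(phi), 0.0],
        ])
        atoms = [AtomRecord(serial=i, name=f"C{i}", element="C",
                            residue_name="TOR", residue_index=1)
                 for i in range(4)]
        system = ParameterizedSystem(
            atoms=atoms, coordinates=coords,
            dihedrals=[Dihedral(0, 1, 2, 3, force_k=k, periodicity=n,
                                phase=delta)])
        assert mm.torsion_energy(system, coords, np.arange(4)) == \
            pytest.approx(expected, abs=1e-12)

    def test_colinear_geometry_rejected(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        atoms = [AtomRecord(serial=i, name=f"C{i}", element="C",
                            residue_name="TOR", residue_index=1)
                 for i in range(4)]
        system = ParameterizedSystem(
            atoms=atoms, coordinates=coords,
            dihedrals=[Dihedral(0, 1, 2, 3, 1.0, 1, 0.0)])
        with pytest.raises(mm.GeometryError):
            mm.torsion_energy(system, coords, np.arange(4))


class TestInteractionEnergy:
    def test_matches_pairwise_per_frame(self, toy_complex):
        system, bound, _ = toy_complex
        rec = system.selections["receptor"]
        lig = system.selections["ligand"]
        series = mm.interaction_energy(system, rec, lig, bound)
        direct = mm.pairwise_nonbonded(system, rec, lig, bound.coordinates[0],
                                       dielectric=2.0)
        assert series[0].elec == direct.elec
        assert series[0].vdw == direct.vdw

    def test_decay_at_large_separation(self, toy_complex):
        system, bound, _ = toy_complex
        rec = system.selections["receptor"]
        lig = system.selections["ligand"]
        far = bound.coordinates[:1].copy()
        far[0, lig] += 500.0
        series = mm.interaction_energy(system, rec, lig,
                                       Trajectory(far, frame_interval=1.0))
        assert abs(series[0].elec) < 1e-3
        assert abs(series[0].vdw) < 1e-3

    def test_empty_selection_rejected(self, toy_complex):
        system, bound, _ = toy_complex
        with pytest.raises(ValueError):
            mm.interaction_energy(system, np.array([], dtype=int),
                                  system.selections["ligand"], bound)


class TestInternalEnergy:
    def test_rigid_ligand_constant_series(self, toy_complex):
        system, bound, _ = toy_complex
        lig = system.selections["ligand"]
        frames = np.repeat(bound.coordinates[:1], 5, axis=0)
        series = mm.internal_energy(system, lig,
                                    Trajectory(frames, frame_interval=1.0))
        assert np.var(series) == 0.0

    def test_bonded_pair_excluded(self):
        atoms = [AtomRecord(serial=i, name=f"A{i}", element="C",
                            residue_name="LIG", residue_index=1,
                            mm_charge=0.5, lj_epsilon=0.1, lj_rmin_half=1.9)
                 for i in range(2)]
        system = ParameterizedSystem(
            atoms=atoms, coordinates=np.array([[0.0, 0, 0], [1.5, 0, 0]]),
            bonds=[(0, 1)])
        traj = Trajectory(system.coordinates[None], frame_interval=1.0)
        series = mm.internal_energy(system, np.arange(2), traj)
        assert series[0] == 0.0

    def test_matches_brute_force_with_exclusions(self, toy_complex):
        system, bound, _ = toy_complex
        lig = system.selections["ligand"]
        series = mm.internal_energy(system, lig, bound, dielectric=2.0)
        excl, p14 = mm.build_exclusions(system, lig)
        q = system.mm_charges()
        eps, rmh = system.lj_params()
        frame = bound.coordinates[0]
        total = mm.torsion_energy(system, frame, lig)
        for a, i in enumerate(lig):
            for j in lig[a + 1:]:
                key = (min(i, j), max(i, j))
                if key in excl:
                    continue
                r = np.linalg.norm(frame[i] - frame[j])
                total += mm.COULOMB_K * q[i] * q[j] / (2.0 * r)
                em = np.sqrt(eps[i] * eps[j])
                rm = rmh[i] + rmh[j]
                total += em * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        assert series[0] == pytest.approx(total, abs=1e-8)


class TestDeformation:
    def test_identical_series_zero(self):
        s = np.array([1.0, 2.0, 3.0])
        value, sem = mm.deformation_penalty(s, s)
        assert value == 0.0

    def test_constant_shift(self):
        s = np.array([1.0, 2.0, 3.0])
        value, _ = mm.deformation_penalty(s + 3.0, s)
        assert value == pytest.approx(3.0)

    def test_sems_combined_in_quadrature(self):
        _, sem = mm.deformation_penalty(np.ones(4), np.ones(4), 3.0, 4.0)
        assert sem == pytest.approx(5.0)


class TestWaterEnvironmentEnergy:
    def test_isolated_water_zero(self, small_water_box):
        from wetbind.synthetic import _water_system
        system = _water_system(1)
        frame = np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        assert mm.water_environment_energy(system, 0, frame) == 0.0

    def test_dimer_matches_hand_sum(self):
        from wetbind.synthetic import _water_system, WATER_TEMPLATE
        system = _water_system(2)
        frame = np.vstack([WATER_TEMPLATE, WATER_TEMPLATE + [2.8, 0, 0]])
        q = system.mm_charges()
        eps, rmh = system.lj_params()
        expected = 0.0
        for i in range(3):
            for j in range(3, 6):
                r = np.linalg.norm(frame[i] - frame[j])
                expected += mm.COULOMB_K * q[i] * q[j] / r
                em = np.sqrt(eps[i] * eps[j])
                rm = rmh[i] + rmh[j]
                if em > 0:
                    expected += em * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        got = mm.water_environment_energy(system, 0, frame)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_batch_equals_per_water_calls(self, small_water_box):
        system, traj = small_water_box
        sub = Trajectory(traj.coordinates[:2], frame_interval=1.0,
                         box=traj.box)
        batch = mm.environment_energies_all_waters(system, sub)
        keys = system.water_residues()
        for f in range(2):
            for w in (0, 10, 63):
                single = mm.water_environment_energy(
                    system, keys[w], sub.coordinates[f], box=sub.frame_box(f))
                assert batch[f, w] == pytest.approx(single, rel=1e-10)
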