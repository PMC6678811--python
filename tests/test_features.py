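"""Structural statistics: closed forms, dual-formula/brute-force oracles,
and the range/monotonicity invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinemsm as km
from kinemsm.features import GAS_CONSTANT_CAL, _kabsch_rmsd
from kinemsm.trajectory import Trajectory


def point_trajectory(xyz, radii=None, residue_step=4):
    """n single-atom residues, spaced far apart in sequence so any pair is a
    valid long-range contact candidate."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    n = xyz.shape[1]
    radii = np.full(n, 1.7) if radii is None else np.asarray(radii, dtype=float)
    return Trajectory(
        atom_names=["CA"] * n, elements=["C"] * n,
        residue_indices=np.arange(n) * residue_step,
        residue_names=["ALA"] * n, radii=radii, xyz=xyz,
    )


def oracle_dihedral(p0, p1, p2, p3):
    """Independent formula: atan2 of cross products of bond vectors."""
    u1 = np.subtract(p1, p0)
    u2 = np.subtract(p2, p1)
    u3 = np.subtract(p3, p2)
    n1 = np.cross(u1, u2)
    n2 = np.cross(u2, u3)
    u2n = u2 / np.linalg.norm(u2)
    y = np.dot(np.cross(n1, n2), u2n)
    x = np.dot(n1, n2)
    return np.degrees(np.arctan2(y, x))


class TestDihedrals:
    def test_planar_cis_is_zero(self):
        assert km.dihedral_angle([0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_is_plus_ninety(self):
        # fixes the right-handed sign convention
        assert km.dihedral_angle([0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]) == \
            pytest.approx(90.0, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=12, max_size=12))
    def test_matches_independent_formula(self, flat):
        pts = np.array(flat).reshape(4, 3)
        # reject degenerate geometries the same way the implementation does
        if min(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(3)) < 1e-3:
            return
        ref = oracle_dihedral(*pts)
        val = km.dihedral_angle(*pts)
        if np.isnan(val):
            return
        diff = (val - ref + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-6

    def test_rigid_rotation_leaves_dihedrals_unchanged(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4, 3))
        ref = km.dihedral_angle(*pts)
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=1).as_matrix()
        rotated = pts @ R.T + np.array([1.0, -2.0, 3.0])
        assert km.dihedral_angle(*rotated) == pytest.approx(ref, abs=1e-6)

    def test_collinear_atoms_marked_undefined(self):
        val = km.dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])
        assert np.isnan(val)

    def test_sincos_encoding_doubles_columns(self):
        traj = km.build_backbone_trajectory(np.full((3, 6), -60.0),
                                            np.full((3, 6), -45.0))
        ang = km.compute_backbone_dihedrals(traj, encoding="angles")
        sc = km.compute_backbone_dihedrals(traj, encoding="sincos")
        assert sc.values.shape[1] == 2 * ang.values.shape[1]
        assert np.allclose(sc.values[:, 0], np.sin(np.deg2rad(ang.values[:, 0])))


class TestHelicity:
    def test_all_helical_frames_give_one(self):
        traj = km.build_backbone_trajectory(np.full((10, 8), -60.0),
                                            np.full((10, 8), -45.0))
        prof = km.compute_helicity(traj)
        assert np.allclose(prof.values, 1.0)

    def test_beta_region_gives_zero(self):
        traj = km.build_backbone_trajectory(np.full((10, 8), -135.0),
                                            np.full((10, 8), 135.0))
        prof = km.compute_helicity(traj)
        assert np.allclose(prof.values, 0.0)

    def test_half_helical_mixture_gives_half(self):
        helix = km.build_backbone_trajectory(np.full((10, 8), -60.0),
                                             np.full((10, 8), -45.0))
        coil = km.build_backbone_trajectory(np.full((10, 8), -135.0),
                                            np.full((10, 8), 135.0))
        mixed = Trajectory(
            atom_names=helix.atom_names, elements=helix.elements,
            residue_indices=helix.residue_indices,
            residue_names=helix.residue_names, radii=helix.radii,
            xyz=np.concatenate([helix.xyz, coil.xyz]),
        )
        prof = km.compute_helicity(mixed)
        assert np.allclose(prof.values, 0.5)

    def test_short_runs_are_suppressed(self):
        # only two adjacent residues helical -> below the 3-residue rule
        phi = np.full((5, 8), -135.0)
        psi = np.full((5, 8), 135.0)
        phi[:, 3:5] = -60.0
        psi[:, 3:5] = -45.0
        traj = km.build_backbone_trajectory(phi, psi)
        prof = km.compute_helicity(traj)
        assert np.allclose(prof.values, 0.0)

    def test_per_run_dispersion_reported(self):
        helix = km.build_backbone_trajectory(np.full((20, 8), -60.0),
                                             np.full((20, 8), -45.0))
        traj = Trajectory(
            atom_names=helix.atom_names, elements=helix.elements,
            residue_indices=helix.residue_indices,
            residue_names=helix.residue_names, radii=helix.radii,
            xyz=helix.xyz, boundaries=(10,),
        )
        prof = km.compute_helicity(traj)
        assert np.allclose(prof.stderr, 0.0)  # identical runs -> no spread


class TestNativeContacts:
    def make_helix(self, n_frames=1, n_res=12):
        return km.build_backbone_trajectory(np.full((n_frames, n_res), -60.0),
                                            np.full((n_frames, n_res), -45.0))

    def test_native_frame_hard_q_is_exactly_one(self):
        traj = self.make_helix()
        ref = km.generate_native_reference(traj, 0)
        q, qi = km.compute_native_contact_fraction(traj, ref, mode="hard")
        assert q[0] == 1.0
        assert np.all(qi.values == 1.0)

    def test_native_frame_soft_q_above_095(self):
        traj = self.make_helix()
        ref = km.generate_native_reference(traj, 0)
        q, _ = km.compute_native_contact_fraction(traj, ref, mode="soft")
        assert q[0] >= 0.95

    def test_fully_displaced_structure_breaks_all_contacts(self):
        traj = self.make_helix()
        ref = km.generate_native_reference(traj, 0)
        blown = Trajectory(
            atom_names=traj.atom_names, elements=traj.elements,
            residue_indices=traj.residue_indices,
            residue_names=traj.residue_names, radii=traj.radii,
            xyz=traj.xyz * 10.0,
        )
        q_soft, _ = km.compute_native_contact_fraction(blown, ref, mode="soft")
        q_hard, _ = km.compute_native_contact_fraction(blown, ref, mode="hard")
        assert q_soft[0] < 0.01
        assert q_hard[0] == 0.0

    def test_logistic_midpoint_contributes_half(self):
        # one pair at native distance 2.0 Å, frame at exactly λ·r0
        native = point_trajectory(np.array([[0, 0, 0], [2.0, 0, 0]]))
        ref = km.NativeReference(pairs=[[0, 1]], r0=[2.0], residue_pairs=[[0, 4]])
        frame = point_trajectory(np.array([[0, 0, 0], [1.8 * 2.0, 0, 0]]))
        q, _ = km.compute_native_contact_fraction(frame, ref, mode="soft")
        assert q[0] == pytest.approx(0.5, abs=1e-12)
        assert native is not frame

    def test_empty_reference_gives_q_one_by_convention(self):
        traj = self.make_helix()
        ref = km.NativeReference(pairs=np.empty((0, 2)), r0=np.empty(0),
                                 residue_pairs=np.empty((0, 2)))
        q, qi = km.compute_native_contact_fraction(traj, ref)
        assert np.all(q == 1.0) and np.all(qi.values == 1.0)


class TestDihedralEntropy:
    def test_delta_distribution_has_zero_entropy(self):
        traj = km.build_backbone_trajectory(np.full((50, 6), -60.0),
                                            np.full((50, 6), -45.0))
        prof = km.compute_dihedral_entropy(traj, bins_per_angle=24)
        assert np.allclose(prof.values, 0.0, atol=1e-12)

    def test_two_equal_cells_give_R_ln2(self):
        phi = np.full((50, 6), -60.0)
        psi = np.where(np.arange(50)[:, None] % 2 == 0, -45.0, 120.0)
        psi = np.broadcast_to(psi, (50, 6)).copy()
        traj = km.build_backbone_trajectory(phi, psi)
        prof = km.compute_dihedral_entropy(traj, bins_per_angle=24)
        expected = GAS_CONSTANT_CAL * np.log(2)
        # interior residues see both cells; termini lack one angle but still
        # have defined histograms from the other partner
        interior = (prof.residue_indices >= 1) & (prof.residue_indices <= 4)
        assert np.allclose(prof.values[interior], expected, atol=1e-9)
        assert expected == pytest.approx(1.377, abs=1e-3)

    def test_uniform_over_all_cells_gives_R_ln_bins_squared(self):
        bins = 24
        centers = -180.0 + (np.arange(bins) + 0.5) * (360.0 / bins)
        phi_c, psi_c = np.meshgrid(centers, centers, indexing="ij")
        phi = np.repeat(phi_c.ravel()[:, None], 6, axis=1)
        psi = np.repeat(psi_c.ravel()[:, None], 6, axis=1)
        traj = km.build_backbone_trajectory(phi, psi)
        prof = km.compute_dihedral_entropy(traj, bins_per_angle=bins)
        expected = GAS_CONSTANT_CAL * np.log(bins * bins)
        interior = (prof.residue_indices >= 1) & (prof.residue_indices <= 4)
        assert np.allclose(prof.values[interior], expected, atol=1e-9)
        assert expected == pytest.approx(12.63, abs=5e-3)

    def test_few_frames_flagged_unreliable(self):
        traj = km.build_backbone_trajectory(np.full((5, 6), -60.0),
                                            np.full((5, 6), -45.0))
        prof = km.compute_dihedral_entropy(traj)
        assert np.all(prof.unreliable)

    def test_too_few_bins_rejected(self):
        traj = km.build_backbone_trajectory(np.full((5, 6), -60.0),
                                            np.full((5, 6), -45.0))
        with pytest.raises(ValueError):
            km.compute_dihedral_entropy(traj, bins_per_angle=1)


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        traj = point_trajectory(np.zeros((1, 1, 3)), radii=[1.6])
        prof = km.compute_sasa(traj, probe=1.4, n_sphere_points=960)
        assert prof.values[0] == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_distant_atoms_keep_full_area(self):
        traj = point_trajectory(np.array([[[0, 0, 0], [20.0, 0, 0]]]),
                                radii=[1.6, 1.6])
        prof = km.compute_sasa(traj, probe=1.4, n_sphere_points=240)
        full = 4 * np.pi * 3.0**2
        assert np.allclose(prof.values, full, rtol=1e-12)

    def test_fully_buried_atom_has_zero_area(self):
        traj = point_trajectory(np.array([[[0, 0, 0], [0.2, 0, 0]]]),
                                radii=[0.4, 3.0])
        prof = km.compute_sasa(traj, probe=1.0, n_sphere_points=240)
        assert prof.values[0] == 0.0

    def test_occluder_never_increases_area(self):
        rng = np.random.default_rng(4)
        base_xyz = rng.uniform(-3, 3, size=(1, 5, 3))
        base = point_trajectory(base_xyz)
        with_extra = point_trajectory(
            np.concatenate([base_xyz, [[[0.5, 0.5, 0.5]]]], axis=1))
        a = km.compute_sasa(base, n_sphere_points=240)
        b = km.compute_sasa(with_extra, n_sphere_points=240)
        assert np.all(b.values[:-1] <= a.values + 1e-9)

    def test_point_count_floor(self):
        traj = point_trajectory(np.zeros((1, 1, 3)))
        with pytest.raises(ValueError):
            km.compute_sasa(traj, n_sphere_points=10)


class TestRMSD:
    def test_identical_frames_give_zero(self):
        traj = km.build_backbone_trajectory(np.full((3, 5), -60.0),
                                            np.full((3, 5), -45.0))
        assert np.allclose(km.compute_rmsd(traj, 0), 0.0, atol=1e-9)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        xyz = rng.normal(size=(1, 10, 3))
        R = Rotation.random(random_state=5).as_matrix()
        moved = xyz @ R.T + np.array([3.0, -1.0, 2.0])
        traj = point_trajectory(np.concatenate([xyz, moved]))
        series = km.compute_rmsd(traj, ref_frame=0, superpose=True)
        assert series[1] == pytest.approx(0.0, abs=1e-6)
        raw = km.compute_rmsd(traj, ref_frame=0, superpose=False)
        assert raw[1] > 1.0

    def test_matches_quaternion_grid_search(self):
        rng = np.random.default_rng(9)
        P = rng.normal(size=(4, 3))
        Q = rng.normal(size=(4, 3))
        traj = point_trajectory(np.stack([Q, P]))
        fast = km.compute_rmsd(traj, ref_frame=0, superpose=True)[1]
        # brute force over rotations: random unit quaternions, fine sampling
        from scipy.spatial.transform import Rotation

        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        quats = rng.normal(size=(200_000, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        mats = Rotation.from_quat(quats).as_matrix()
        rot = np.einsum("rij,nj->rni", mats, Pc)
        rmsds = np.sqrt(np.mean(np.sum((rot - Qc) ** 2, axis=2), axis=1))
        assert fast <= rmsds.min() + 1e-9
        assert fast == pytest.approx(rmsds.min(), abs=1e-3)

    def test_superposition_needs_three_atoms(self):
        traj = point_trajectory(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="3 atoms"):
            km.compute_rmsd(traj, 0, selection=np.array([0, 1]), superpose=True)


class TestContactProbability:
    def test_always_within_cutoff_is_one(self):
        traj = point_trajectory(np.zeros((3, 2, 3)))
        prof = km.compute_contact_probability(traj, np.array([0]), np.array([1]),
                                              cutoff=1.0)
        assert np.all(prof.values == 1.0)

    def test_never_within_cutoff_is_zero(self):
        xyz = np.zeros((3, 2, 3))
        xyz[:, 1, 0] = 50.0
        traj = point_trajectory(xyz)
        prof = km.compute_contact_probability(traj, np.array([0]), np.array([1]),
                                              cutoff=1.0)
        assert np.all(prof.values == 0.0)

    def test_contact_in_one_of_two_frames_is_half(self):
        xyz = np.zeros((2, 2, 3))
        xyz[1, 1, 0] = 50.0
        traj = point_trajectory(xyz)
        prof = km.compute_contact_probability(traj, np.array([0]), np.array([1]),
                                              cutoff=1.0)
        assert prof.values[0] == 0.5

    def test_empty_selection_rejected(self):
        traj = point_trajectory(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError):
            km.compute_contact_probability(traj, np.array([], dtype=int),
                                           np.array([1]))
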