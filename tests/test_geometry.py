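"""Superposition, RMSD/RMSF, distances, ring stacking, loop detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dimertraj import (
    Frame, RMSFProfile, SyntheticSpec, Trajectory,
    build_toy_dimer, detect_loop_opening, distance_series, generate_trajectory,
    kabsch_superpose, ring_stacking, rmsd_series, rmsf,
)
from dimertraj.geometry import apply_transform


def _random_coords(rng, n=12, scale=8.0):
    return rng.normal(0, scale, size=(n, 3))


class TestKabsch:
    def test_identity_on_equal_structures(self, rng):
        x = _random_coords(rng)
        rot, trans, val = kabsch_superpose(x, x)
        assert val == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self, rng):
        x = _random_coords(rng)
        true_rot = Rotation.random(random_state=7).as_matrix()
        y = x @ true_rot.T + np.array([3.0, -2.0, 5.0])
        rot, trans, val = kabsch_superpose(x, y)
        assert val == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(rot, true_rot, atol=1e-8)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_beats_brute_force_random_rigid_placements(self, rng):
        """Optimal RMSD can never exceed the best of 1e5 random rotations
        (each with its optimal centroid-matching translation)."""
        x = _random_coords(rng, n=5, scale=4.0)
        y = _random_coords(rng, n=5, scale=4.0)
        _, _, optimal = kabsch_superpose(x, y)
        rots = Rotation.random(100_000, random_state=11).as_matrix()
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        moved = np.einsum("rij,nj->rni", rots, xc)
        rmsds = np.sqrt(((moved - yc) ** 2).sum(axis=(1, 2)) / 5.0)
        assert optimal <= rmsds.min() + 1e-9

    def test_collinear_fit_set_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line + 1.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(angles=st.lists(st.floats(-np.pi, np.pi), min_size=3, max_size=3),
           shift=st.lists(st.floats(-50.0, 50.0), min_size=3, max_size=3))
    def test_arbitrary_rotation_always_recovered(self, angles, shift):
        """Property: any proper rotation + translation of a rigid point set
        is undone exactly (RMSD 0, inverse rotation returned)."""
        rng = np.random.default_rng(12)
        x = rng.normal(0, 5, size=(8, 3))
        true_rot = Rotation.from_euler("xyz", angles).as_matrix()
        y = x @ true_rot.T + np.asarray(shift)
        rot, _, val = kabsch_superpose(x, y)
        assert val == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(rot, true_rot, atol=1e-7)

    def test_rmsd_invariant_under_common_rigid_transform(self, rng):
        x = _random_coords(rng)
        y = _random_coords(rng)
        _, _, before = kabsch_superpose(x, y)
        rot = Rotation.random(random_state=3).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        _, _, after = kabsch_superpose(
            apply_transform(x, rot, t), apply_transform(y, rot, t))
        assert after == pytest.approx(before, abs=1e-8)


class TestRMSDSeries:
    def test_zero_on_reference_and_matches_fit_rmsd(self, rng):
        x = _random_coords(rng, n=20)
        frames = np.stack([x, apply_transform(
            x, Rotation.random(random_state=5).as_matrix(), np.ones(3))])
        traj = Trajectory(frames, np.array([0.0, 1.0]), "WT")
        idx = np.arange(20)
        series = rmsd_series(traj, Frame(x), idx, idx)
        assert series.values[0] == pytest.approx(0.0, abs=1e-10)
        # on the fit set the series equals the Kabsch fit RMSD frame by frame
        for k in range(2):
            _, _, fit_val = kabsch_superpose(frames[k], x)
            assert series.values[k] == pytest.approx(fit_val, abs=1e-10)

    def test_planted_rigid_displacement_reads_exactly(self, rng):
        protein = _random_coords(rng, n=30)
        ligand = _random_coords(rng, n=6, scale=2.0) + 20.0
        ref = np.vstack([protein, ligand])
        displaced = ref.copy()
        displaced[30:] += np.array([0.0, 0.0, 2.5])  # rigid 2.5 A shift
        traj = Trajectory(np.stack([displaced] * 3),
                          np.arange(3, dtype=float), "WT")
        series = rmsd_series(traj, Frame(ref), np.arange(30),
                             np.arange(30, 36))
        assert np.allclose(series.values, 2.5, atol=1e-10)

    def test_empty_measure_set_rejected(self, rng):
        x = _random_coords(rng)
        traj = Trajectory(x[None], np.array([0.0]), "WT")
        with pytest.raises(ValueError, match="empty measure"):
            rmsd_series(traj, Frame(x), np.arange(12), np.array([], dtype=int))


class TestRMSF:
    def test_static_trajectory_gives_zero(self, tiny_system):
        top, ref = tiny_system
        traj = Trajectory(np.stack([ref.coords] * 4),
                          np.arange(4, dtype=float), "WT")
        ca = np.array([i for i in range(top.n_atoms)
                       if top.names[i] == "CA"])
        prof = rmsf(traj, top, ca)
        assert np.allclose(prof.values, 0.0, atol=1e-9)

    def test_iid_jitter_converges_to_sigma_sqrt3(self, tiny_system):
        """Isotropic Gaussian jitter of SD 0.5 A/coordinate gives a per-atom
        RMSF of 0.5*sqrt(3) ~ 0.866 A."""
        spec = SyntheticSpec(residues_per_monomer=16, loop_range=(3, 4),
                             n_frames=800, seed=1, jitter_sd=0.5,
                             amplitude_sd=0.0, delta=0.0, k_on=1.0, k_off=0.0)
        top, ref = build_toy_dimer(spec)
        traj = generate_trajectory(top, ref, spec, "WT")
        ca = np.array([i for i in range(top.n_atoms)
                       if top.names[i] == "CA"])
        prof = rmsf(traj, top, ca)
        expected = 0.5 * np.sqrt(3.0)
        assert np.abs(prof.values.mean() - expected) / expected < 0.05

    def test_monomer_averaging_and_frame_order_invariance(self, tiny_system,
                                                          tiny_spec):
        top, ref = tiny_system
        traj = generate_trajectory(top, ref, tiny_spec, "WT")
        ca = np.array([i for i in range(top.n_atoms)
                       if top.names[i] == "CA"])
        prof = rmsf(traj, top, ca, average_monomers=True)
        assert prof.values.size == 16          # one value per residue number
        perm = np.random.default_rng(4).permutation(traj.n_frames)
        shuffled = Trajectory(traj.coords[perm], traj.times, "WT")
        prof2 = rmsf(shuffled, top, ca, average_monomers=True)
        assert np.allclose(prof.values, prof2.values, atol=1e-9)

    def test_two_state_loop_motion_dominates_profile(self):
        spec = SyntheticSpec(residues_per_monomer=16, loop_range=(3, 4),
                             n_frames=800, seed=3, loop_opening=10.0,
                             loop_onset_fraction=0.5, amplitude_sd=0.0,
                             delta=0.0, k_on=1.0, k_off=0.0)
        top, ref = build_toy_dimer(spec)
        traj = generate_trajectory(top, ref, spec, "WT")
        ca = np.array([i for i in range(top.n_atoms)
                       if top.names[i] == "CA"])
        scaffold = np.array([i for i in ca if not 3 <= top.resnums[i] <= 4])
        prof = rmsf(traj, top, ca, fit_indices=scaffold,
                    average_monomers=True)
        loop = np.isin(prof.resnums, [3, 4])
        assert prof.values[loop].min() >= 4 * prof.values[~loop].max()


class TestDistances:
    def test_constant_pair_distance(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 3.0
        traj = Trajectory(coords, np.arange(3, dtype=float), "WT")
        s = distance_series(traj, 0, 1)
        assert np.allclose(s.values, 3.0)

    def test_triad_geometry_reports_3A_pairs(self, tiny_system):
        """The planted catalytic-triad stand-ins sit at the ideal 3 A
        pairwise spacing in the reference frame."""
        top, ref = tiny_system
        traj = Trajectory(ref.coords[None], np.array([0.0]), "WT")
        t1, t2, t3 = top.metadata["triad_residues"]
        i = top.index_of("A", t1, "NE2")
        j = top.index_of("A", t2, "OG1")
        k = top.index_of("A", t3, "ND1")
        assert distance_series(traj, i, j).values[0] == pytest.approx(3.0)
        assert distance_series(traj, j, k).values[0] == pytest.approx(3.0)

    def test_centroid_of_singleton_equals_atom(self, rng):
        coords = rng.normal(size=(2, 4, 3))
        traj = Trajectory(coords, np.arange(2, dtype=float), "WT")
        assert np.allclose(distance_series(traj, 0, 1).values,
                           distance_series(traj, [0], [1]).values)

    def test_identical_atoms_rejected(self, rng):
        traj = Trajectory(rng.normal(size=(1, 4, 3)), np.array([0.0]), "WT")
        with pytest.raises(ValueError, match="identical"):
            distance_series(traj, 2, 2)


class TestRingStacking:
    @staticmethod
    def _hexagon(center, normal_axis=0, radius=1.4):
        pts = []
        for k in range(6):
            ang = 2 * np.pi * k / 6
            v = np.zeros(3)
            v[(normal_axis + 1) % 3] = radius * np.cos(ang)
            v[(normal_axis + 2) % 3] = radius * np.sin(ang)
            pts.append(np.asarray(center, dtype=float) + v)
        return np.array(pts)

    def test_parallel_hexagons_at_3p8(self):
        a = self._hexagon([0, 0, 0])
        b = self._hexagon([3.8, 0, 0])
        traj = Trajectory(np.vstack([a, b])[None], np.array([0.0]), "WT")
        sep, ang = ring_stacking(traj, np.arange(6), np.arange(6, 12))
        assert sep.values[0] == pytest.approx(3.8, abs=1e-10)
        assert ang.values[0] == pytest.approx(0.0, abs=1e-8)

    def test_perpendicular_rings(self):
        a = self._hexagon([0, 0, 0], normal_axis=0)
        b = self._hexagon([5.0, 0, 0], normal_axis=2)
        traj = Trajectory(np.vstack([a, b])[None], np.array([0.0]), "WT")
        _, ang = ring_stacking(traj, np.arange(6), np.arange(6, 12))
        assert ang.values[0] == pytest.approx(90.0, abs=1e-8)

    @pytest.mark.parametrize("theta", [5.0, 30.0, 60.0])
    def test_known_tilt_recovered(self, theta):
        a = self._hexagon([0, 0, 0])
        rot = Rotation.from_euler("y", theta, degrees=True).as_matrix()
        b = self._hexagon([0, 0, 0]) @ rot.T + np.array([6.0, 0, 0])
        traj = Trajectory(np.vstack([a, b])[None], np.array([0.0]), "WT")
        _, ang = ring_stacking(traj, np.arange(6), np.arange(6, 12))
        assert ang.values[0] == pytest.approx(theta, abs=1e-6)

    def test_symmetry_and_atom_order_invariance(self, rng):
        a = self._hexagon([0, 0, 0])
        b = self._hexagon([3.0, 1.0, 0.5], normal_axis=1)
        traj = Trajectory(np.vstack([a, b])[None], np.array([0.0]), "WT")
        sep1, ang1 = ring_stacking(traj, np.arange(6), np.arange(6, 12))
        sep2, ang2 = ring_stacking(traj, np.arange(6, 12), np.arange(6))
        perm = rng.permutation(6)
        sep3, ang3 = ring_stacking(traj, perm, np.arange(6, 12))
        assert ang1.values[0] == pytest.approx(ang2.values[0], abs=1e-9)
        assert sep1.values[0] == pytest.approx(sep2.values[0], abs=1e-9)
        assert ang1.values[0] == pytest.approx(ang3.values[0], abs=1e-9)


class TestLoopOpening:
    @staticmethod
    def _profile(values, label):
        return RMSFProfile(np.arange(1, len(values) + 1),
                           np.asarray(values, dtype=float), label)

    def test_identical_profiles_not_detected(self):
        p = self._profile([0.3] * 10, "bound")
        report = detect_loop_opening(p, p, (4, 6))
        assert not report.detected
        assert np.allclose(report.delta_rmsf, 0.0)

    def test_planted_12A_detected_5A_not(self):
        bound = self._profile([0.3] * 10, "bound")
        open12 = self._profile([0.3] * 3 + [12.3] * 3 + [0.3] * 4, "unbound")
        open5 = self._profile([0.3] * 3 + [5.3] * 3 + [0.3] * 4, "unbound")
        assert detect_loop_opening(bound, open12, (4, 6)).detected
        assert not detect_loop_opening(bound, open5, (4, 6)).detected

    def test_loop_outside_profile_rejected(self):
        p = self._profile([0.3] * 10, "x")
        with pytest.raises(ValueError, match="outside"):
            detect_loop_opening(p, p, (9, 12))
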