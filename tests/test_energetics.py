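"""Force-field terms, GB-OBC2 limits, LCPO areas, EM/EE/EL/ET accounting,
and the per-residue pairwise decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dimertraj import (
    Frame, Trajectory, generate_trajectory,
    bonded_energy, coulomb_lj_energy, decompose_em_ee_el,
    effective_born_radii, gb_polar_energy, born_self_energy,
    load_reference_energy_table, pairwise_residue_decomposition, sasa_lcpo,
    system_energy,
)
from dimertraj.energetics import (
    COULOMB_CONSTANT, EPS_OUT, GB_OFFSET, PROBE_RADIUS, EnergyError,
)
from dimertraj.geometry import apply_transform
from dimertraj.topology import BondTerm, Topology


def _ion_topology(charges, radii, eps=None, rmin_half=None):
    """Bare point-particle topology (no bonds) on monomer A."""
    n = len(charges)
    top = Topology(
        names=[f"X{i}" for i in range(n)],
        elements=["O"] * n,
        resnums=np.arange(1, n + 1),
        resnames=["ION"] * n,
        groups=["A"] * n,
    )
    top.charges = np.asarray(charges, dtype=float)
    top.lj_eps = np.zeros(n) if eps is None else np.asarray(eps, dtype=float)
    top.lj_rmin_half = np.ones(n) if rmin_half is None else \
        np.asarray(rmin_half, dtype=float)
    top.gb_radius = np.asarray(radii, dtype=float)
    top.gb_screen = np.full(n, 0.8)
    top.lcpo = np.tile([0.77914, -0.25262, -0.0016056, 0.00035071], (n, 1))
    top.bond_terms = []
    return top


class TestBonded:
    def test_equilibrium_geometry_is_zero(self, tiny_system):
        top, ref = tiny_system
        assert bonded_energy(top, ref) == pytest.approx(0.0, abs=1e-12)

    def test_single_stretched_bond_is_k_delta_squared(self):
        top = _ion_topology([0.0, 0.0], [1.5, 1.5])
        top.bonds = [(0, 1)]
        top.bond_terms = [BondTerm(0, 1, k=300.0, r0=1.0)]
        frame = Frame(np.array([[0.0, 0, 0], [1.25, 0, 0]]))
        assert bonded_energy(top, frame) == pytest.approx(300.0 * 0.25 ** 2)

    def test_missing_bond_parameter_named(self):
        top = _ion_topology([0.0, 0.0], [1.5, 1.5])
        top.bonds = [(0, 1)]
        top.bond_terms = [BondTerm(0, 1)]
        with pytest.raises(EnergyError, match="missing bond"):
            bonded_energy(top, Frame(np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]]))


class TestCoulombLJ:
    def test_two_unit_charges_at_3p32(self):
        """Coulomb's constant 332.0637 over 3.32 A is ~100.02 kcal/mol."""
        top = _ion_topology([1.0, 1.0], [1.5, 1.5])
        frame = Frame(np.array([[0.0, 0, 0], [3.32, 0, 0]]))
        coul, lj = coulomb_lj_energy(top, frame)
        assert coul == pytest.approx(COULOMB_CONSTANT / 3.32, rel=1e-12)
        assert coul == pytest.approx(100.019186, abs=1e-5)

    def test_lj_minimum_is_minus_epsilon(self):
        top = _ion_topology([0.0, 0.0], [1.5, 1.5],
                            eps=[0.21, 0.21], rmin_half=[1.7, 1.7])
        frame = Frame(np.array([[0.0, 0, 0], [3.4, 0, 0]]))
        coul, lj = coulomb_lj_energy(top, frame)
        assert coul == 0.0
        assert lj == pytest.approx(-0.21, rel=1e-12)

    def test_neutral_lj_free_atoms_are_zero(self):
        top = _ion_topology([0.0, 0.0], [1.5, 1.5])
        coul, lj = coulomb_lj_energy(
            top, Frame(np.array([[0.0, 0, 0], [4.0, 0, 0]])))
        assert (coul, lj) == (0.0, 0.0)

    def test_overlapping_atoms_rejected(self):
        top = _ion_topology([1.0, 1.0], [1.5, 1.5])
        with pytest.raises(EnergyError, match="overlapping"):
            coulomb_lj_energy(top, Frame(np.zeros((2, 3))))

    def test_one_four_scaling_applied(self):
        """A 4-atom chain: the 1-4 Coulomb pair is divided by 1.2."""
        top = _ion_topology([1.0, 0.0, 0.0, 1.0], [1.5] * 4)
        top.bonds = [(0, 1), (1, 2), (2, 3)]
        top.bond_terms = [BondTerm(i, j, 300.0, 1.0) for i, j in top.bonds]
        x = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])
        coul, _ = coulomb_lj_energy(top, Frame(x))
        assert coul == pytest.approx(COULOMB_CONSTANT / 4.5 / 1.2, rel=1e-12)


class TestBornRadii:
    def test_isolated_atom_reduces_to_offset_radius(self):
        top = _ion_topology([1.0], [1.5])
        reff = effective_born_radii(top, Frame(np.zeros((1, 3))))
        assert reff[0] == pytest.approx(1.5 - GB_OFFSET, rel=1e-12)

    def test_distant_pair_descreening_decays(self):
        top = _ion_topology([1.0, 1.0], [1.5, 1.5])
        frame = Frame(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        reff = effective_born_radii(top, frame)
        assert np.all(np.abs(reff - (1.5 - GB_OFFSET)) / (1.5 - GB_OFFSET)
                      < 0.01)

    def test_buried_atom_grows_beyond_isolated_value(self, rng):
        # central atom caged by 12 neighbours at 3 A
        shell = rng.normal(size=(12, 3))
        shell = 3.0 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        top = _ion_topology([0.0] * 13, [1.5] * 13)
        reff = effective_born_radii(top, Frame(coords))
        assert reff[0] > 1.5 - GB_OFFSET


class TestGBPolar:
    def test_single_ion_matches_born_closed_form(self):
        top = _ion_topology([1.0], [1.6])
        e = gb_polar_energy(top, Frame(np.zeros((1, 3))))
        reff = 1.6 - GB_OFFSET
        assert e == pytest.approx(born_self_energy(1.0, reff), rel=1e-12)

    def test_two_distant_ions_match_summed_born_terms(self):
        """At 50 A, f_GB -> r, so the GB energy equals the closed-form sum of
        the two Born self terms plus the screened Coulomb cross term to
        better than 0.1%."""
        top = _ion_topology([1.0, -1.0], [1.5, 1.7])
        frame = Frame(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        e = gb_polar_energy(top, frame)
        r1, r2 = 1.5 - GB_OFFSET, 1.7 - GB_OFFSET
        closed = (born_self_energy(1.0, r1) + born_self_energy(-1.0, r2)
                  - COULOMB_CONSTANT * (1.0 - 1.0 / EPS_OUT) * (-1.0) / 50.0)
        assert abs(e - closed) / abs(closed) < 1e-3

    def test_zero_charges_give_zero(self, tiny_system):
        top, ref = tiny_system
        neutral = _ion_topology([0.0, 0.0], [1.5, 1.5])
        assert gb_polar_energy(
            neutral, Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]))) == 0.0

    def test_solvent_dielectric_one_switches_solvation_off(self, tiny_system):
        top, ref = tiny_system
        assert gb_polar_energy(top, ref, eps_out=1.0) == pytest.approx(
            0.0, abs=1e-12)


class TestLCPO:
    def test_isolated_atom_area(self):
        top = _ion_topology([0.0], [1.5])
        total, per_atom = sasa_lcpo(top, Frame(np.zeros((1, 3))))
        expected = 0.77914 * 4 * np.pi * (1.5 + PROBE_RADIUS) ** 2
        assert total == pytest.approx(expected, rel=1e-12)

    def test_separated_atoms_are_additive(self):
        top = _ion_topology([0.0, 0.0], [1.5, 1.5])
        far = Frame(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        total, _ = sasa_lcpo(top, far)
        single = 0.77914 * 4 * np.pi * (1.5 + PROBE_RADIUS) ** 2
        assert total == pytest.approx(2 * single, rel=1e-12)

    def test_overlap_strictly_reduces_area(self):
        top = _ion_topology([0.0, 0.0], [1.5, 1.5])
        far, _ = sasa_lcpo(top, Frame(np.array([[0.0, 0, 0], [50.0, 0, 0]])))
        near, _ = sasa_lcpo(top, Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]])))
        assert near < far


class TestSystemEnergy:
    def test_total_is_exact_sum_of_terms(self, tiny_system):
        top, ref = tiny_system
        rec = system_energy(top, ref)
        assert rec.total == rec.bonded + rec.coulomb + rec.lj + rec.gb \
            + rec.nonpolar
        assert np.isfinite(rec.total)

    def test_invariant_under_rigid_transform(self, tiny_system):
        top, ref = tiny_system
        rec = system_energy(top, ref)
        rot = Rotation.random(random_state=9).as_matrix()
        moved = Frame(apply_transform(ref.coords, rot,
                                      np.array([10.0, -4.0, 6.0])))
        rec2 = system_energy(top, moved)
        assert rec2.total == pytest.approx(rec.total, abs=1e-8)

    def test_doubling_charges_scales_coulomb_and_gb_fourfold(self,
                                                             tiny_system):
        top, ref = tiny_system
        rec = system_energy(top, ref)
        doubled = _clone_with_charges(top, 2.0 * top.charges)
        rec2 = system_energy(doubled, ref)
        assert rec2.coulomb == pytest.approx(4.0 * rec.coulomb, rel=1e-10)
        assert rec2.gb == pytest.approx(4.0 * rec.gb, rel=1e-10)
        assert rec2.lj == pytest.approx(rec.lj, rel=1e-10)
        assert rec2.sasa_area == pytest.approx(rec.sasa_area, rel=1e-12)


def _clone_with_charges(top, charges):
    import copy
    clone = copy.copy(top)
    clone.metadata = {}
    clone.charges = np.asarray(charges)
    return clone


@pytest.fixture(scope="module")
def breakdown(tiny_system, tiny_spec):
    top, ref = tiny_system
    traj = generate_trajectory(top, ref, tiny_spec, "WT")
    return decompose_em_ee_el(top, traj, last_ns=20.0, stride_ns=1.0)


@pytest.fixture(scope="module")
def pairwise_system(tiny_system, tiny_spec):
    top, ref = tiny_system
    traj = generate_trajectory(top, ref, tiny_spec, "WT")
    return top, traj


class TestDecomposition:
    def test_et_identity_holds_per_frame(self, breakdown):
        assert breakdown.check_identity(tol=1e-9) <= 1e-9
        pf = breakdown.per_frame
        assert np.allclose(pf["EL"], pf["EL1"] + pf["EL2"], atol=1e-9)
        assert np.allclose(pf["EM"], pf["EM1"] + pf["EM2"], atol=1e-9)

    def test_summary_reports_mean_sd_and_block_se(self, breakdown):
        s = breakdown.summary().set_index("term")
        assert (s["sd"] >= 0).all()
        assert s.loc["ET", "mean"] == pytest.approx(
            breakdown.per_frame["ET"].mean())

    def test_infinitely_separated_neutral_monomers_have_zero_ee(self):
        """Two neutral LJ-free monomers 500 A apart: EE = 0, ET = EM."""
        top = _ion_topology([0.0] * 4, [1.5] * 4)
        top.groups = ["A", "A", "B", "B"]
        top.resnums = np.array([1, 2, 1, 2])
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0],
                           [500.0, 0, 0], [503.0, 0, 0]])
        traj = Trajectory(np.stack([coords] * 2),
                          np.arange(2, dtype=float), "WT")
        bd = decompose_em_ee_el(top, traj, last_ns=None, stride_ns=None)
        assert np.allclose(bd.per_frame["EE"], 0.0, atol=1e-6)
        assert np.allclose(bd.per_frame["EL"], 0.0)
        assert np.allclose(bd.per_frame["ET"], bd.per_frame["EM"], atol=1e-6)

    def test_schedule_outside_trajectory_rejected(self, tiny_system,
                                                  tiny_spec):
        top, ref = tiny_system
        traj = generate_trajectory(top, ref, tiny_spec, "WT")
        with pytest.raises(ValueError):
            decompose_em_ee_el(top, traj, last_ns=10.0, stride_ns=5000.0)


class TestReferenceTable:
    def test_reported_energies_sum_to_total_exactly(self):
        """For each of the four systems the reported EM + EE + EL reproduces
        the reported ET at printed precision."""
        table = load_reference_energy_table()
        assert list(table["system"]) == ["WT", "E266K", "R267H", "P300L"]
        resid = (table["EM_kcal"] + table["EE_kcal"] + table["EL_kcal"]
                 - table["ET_kcal"]).abs()
        assert (resid < 0.005).all()       # exact at 0.01 kcal/mol precision
        assert resid.max() == pytest.approx(0.0, abs=1e-9)


class TestPairwiseDecomposition:
    def test_interface_sum_matches_independent_cross_total(self, pairwise_system):
        """Summed per-residue EE contributions equal the monomer-monomer
        cross energy computed by the independent group-pair routines."""
        top, traj = pairwise_system
        mat = pairwise_residue_decomposition(top, traj, "interface",
                                             last_ns=5.0, stride_ns=1.0)
        assert np.allclose(mat.mean.sum(), mat.per_frame_totals.mean(),
                           atol=1e-9)
        from dimertraj.topology import extract_subsystem
        dimer_idx = np.sort(np.concatenate([top.group_indices("A"),
                                            top.group_indices("B")]))
        sub, subtraj = extract_subsystem(top, traj.window(5.0, 1.0),
                                         dimer_idx)
        ga, gb = sub.group_indices("A"), sub.group_indices("B")
        for k in range(subtraj.n_frames):
            frame = Frame(subtraj.coords[k])
            coul, lj = coulomb_lj_energy(sub, frame, ga, gb)
            gb_cross = gb_polar_energy(sub, frame, ga, gb)
            assert mat.per_frame_totals[k] == pytest.approx(
                coul + lj + gb_cross, abs=1e-6)

    def test_ligand_sum_matches_independent_cross_total(self, pairwise_system):
        top, traj = pairwise_system
        mat = pairwise_residue_decomposition(top, traj, "ligand", site="L1",
                                             last_ns=5.0, stride_ns=1.0)
        assert np.allclose(mat.mean.sum(), mat.per_frame_totals.mean(),
                           atol=1e-9)
        from dimertraj.topology import extract_subsystem
        keep = np.sort(np.concatenate([top.group_indices("A"),
                                       top.group_indices("B"),
                                       top.group_indices("L1")]))
        sub, subtraj = extract_subsystem(top, traj.window(5.0, 1.0), keep)
        prot = np.sort(np.concatenate([sub.group_indices("A"),
                                       sub.group_indices("B")]))
        lig = sub.group_indices("L1")
        frame = Frame(subtraj.coords[0])
        coul, lj = coulomb_lj_energy(sub, frame, prot, lig)
        gb_cross = gb_polar_energy(sub, frame, prot, lig)
        assert mat.per_frame_totals[0] == pytest.approx(coul + lj + gb_cross,
                                                        abs=1e-6)

    def test_single_charged_residue_pair_carries_coulomb_ee(self):
        """One charged residue per monomer: that pair accounts for the whole
        electrostatic interface energy."""
        top = _ion_topology([1.0, 0.0, -1.0, 0.0], [1.5] * 4)
        top.groups = ["A", "A", "B", "B"]
        top.resnums = np.array([1, 2, 1, 2])
        coords = np.array([[0.0, 0, 0], [0.0, 4, 0],
                           [6.0, 0, 0], [6.0, 4, 0]])
        traj = Trajectory(coords[None], np.array([0.0]), "fix")
        mat = pairwise_residue_decomposition(top, traj, "interface",
                                             last_ns=None, stride_ns=None)
        res = dict(zip(mat.residues, mat.mean))
        charged = res[("A", 1)] + res[("B", 1)]
        assert charged == pytest.approx(mat.mean.sum(), abs=1e-9)
        assert res[("A", 2)] == pytest.approx(res[("B", 2)], abs=1e-12)

    def test_reference_subtraction_of_self_is_zero(self, pairwise_system):
        top, traj = pairwise_system
        mat = pairwise_residue_decomposition(top, traj, "interface",
                                             last_ns=3.0, stride_ns=1.0)
        rel = mat.relative_to(mat)
        assert np.allclose(rel.mean, 0.0)


def test_subsystem_energy_matches_restricted_double_loop(tiny_system):
    """Intra-ligand Coulomb+LJ of the extracted site equals a brute-force
    double loop over ligand-internal pairs of the full system."""
    from dimertraj.topology import extract_subsystem
    from dimertraj.energetics import _nonbonded_scales
    top, ref = tiny_system
    lig = top.group_indices("L1")
    sub, frame = extract_subsystem(top, ref, lig)
    coul, lj = coulomb_lj_energy(sub, frame)

    coul_scale, lj_scale = _nonbonded_scales(top)
    e_coul = e_lj = 0.0
    for a in range(lig.size):
        for b in range(a + 1, lig.size):
            i, j = lig[a], lig[b]
            r = np.linalg.norm(ref.coords[i] - ref.coords[j])
            e_coul += coul_scale[i, j] * COULOMB_CONSTANT \
                * top.charges[i] * top.charges[j] / r
            rmin = top.lj_rmin_half[i] + top.lj_rmin_half[j]
            eps = np.sqrt(top.lj_eps[i] * top.lj_eps[j])
            e_lj += lj_scale[i, j] * eps * ((rmin / r) ** 12
                                            - 2 * (rmin / r) ** 6)
    assert coul == pytest.approx(e_coul, abs=1e-9)
    assert lj == pytest.approx(e_lj, abs=1e-9)
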