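"""Parameterized toy dimer topologies and trajectories with planted
statistical structure.

The generator emulates, at adjustable scale, the features a microsecond
simulation of a PLP-dependent homodimeric transaminase exhibits:

* a homodimer (mirror-symmetric monomers, author numbering 1..R per monomer)
  with one PLP-like ligand per interface binding site, including a ring of
  six coplanar atoms (one named ``C6``), a charged phosphate-like tail and
  designated hydrogen-bond acceptors;
* a collective *interface-rotation mode* — rigid counter-rotation of the two
  large-domain cores — stored as an explicit orthonormal 3N vector so
  essential-dynamics recovery can be scored by vector overlap, with a
  system-dependent mean displacement (the reference system centered at zero,
  two variants negative, one variant positive);
* a "door"-loop opening event that raises the loop RMSF by a controlled
  amount after a configurable onset;
* two-state (formed 2.9 A / broken 5.5 A) hydrogen-bond donor geometry with
  first-order Markov switching, stationary occupancy k_on / (k_on + k_off);
* isotropic Gaussian thermal jitter on every coordinate.

None of this is physically realistic; it provides exact ground truth that
real trajectories cannot.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .topology import Topology, Frame, Trajectory, BondTerm

# element parameter tables for the toy force field (charge assignment is
# per-site; these cover LJ, GB and LCPO)
LJ_EPS = {"C": 0.1094, "N": 0.17, "O": 0.21, "P": 0.2, "H": 0.0157}
LJ_RMIN_HALF = {"C": 1.908, "N": 1.824, "O": 1.6612, "P": 2.1, "H": 0.6}
GB_RADIUS = {"C": 1.7, "N": 1.55, "O": 1.5, "P": 1.85, "H": 1.2}
GB_SCREEN = {"C": 0.72, "N": 0.79, "O": 0.85, "P": 0.86, "H": 0.85}
LCPO = {
    "C": (0.77887, -0.28063, -0.0012968, 0.00039328),
    "O": (0.77914, -0.25262, -0.0016056, 0.00035071),
    "N": (0.73511, -0.22116, -0.00089148, 0.0002523),
    "P": (0.3865, -0.18249, -0.0036598, 0.0004264),
    "H": (0.0, 0.0, 0.0, 0.0),
}

BOND_K = 300.0  # kcal/mol/A^2, uniform toy bond stiffness

#: planted per-system mean displacement pattern along the interface mode:
#: reference zero, two destabilized variants negative, one positive
DEFAULT_AMPLITUDE_MEANS = {"WT": 0.0, "E266K": -1.0, "P300L": -1.0,
                           "R267H": 2.0}


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults follow the emulated simulation protocol: 413 residues per
    monomer, 1000 frames at 1 ns spacing (analyses window the last 800 ns),
    loop "door" at residues 15-32 opening early in the run.  ``delta`` scales
    the per-system interface-mode means (mean = delta * pattern value).
    """

    residues_per_monomer: int = 413
    ligand_atoms_per_site: int = 12
    delta: float = 3.0                     # A, interface-mode mean scale
    amplitude_sd: float = 1.5              # A
    amplitude_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_MEANS))
    loop_range: tuple[int, int] = (15, 32)
    loop_opening: float = 0.0              # A (SD of planted loop swing)
    loop_onset_fraction: float = 0.1
    k_on: float = 0.3                      # per-frame formation probability
    k_off: float = 0.1
    jitter_sd: float = 0.15                # A, per coordinate
    n_frames: int = 1000
    dt_ns: float = 1.0
    t0_ns: float = 0.0
    seed: int = 1

    n_static_donors: int = 4
    n_switching_donors: int = 2

    def __post_init__(self) -> None:
        if self.amplitude_sd < 0 or self.jitter_sd < 0 or self.loop_opening < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.k_on <= 1 and 0 <= self.k_off <= 1):
            raise ValueError("switch rates are per-frame probabilities in [0,1]")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.ligand_atoms_per_site < 12:
            raise ValueError("ligand template needs at least 12 atoms per site")
        if self.n_static_donors > 4 or self.n_switching_donors > 2:
            raise ValueError("at most 4 static and 2 switching donors per site")
        if self.residues_per_monomer < max(self.loop_range[1], 16):
            raise ValueError(
                f"residues per monomer ({self.residues_per_monomer}) must "
                f"cover the loop range {self.loop_range} and the designated "
                f"special residues (>= 16)")


# ligand template: pyridine-like ring (N1, C2..C6), hydroxyl/aldehyde
# oxygens O3/O4, bridge-free phosphate tail P + O1P/O2P/O3P
_RING_NAMES = ["N1", "C2", "C3", "C4", "C5", "C6"]
_STATIC_ACCEPTORS = ["O1P", "O2P", "O3P", "N1"]
_SWITCH_ACCEPTORS = ["O3", "O4"]


def _ligand_template(n_atoms: int) -> tuple[list[str], list[str], np.ndarray,
                                            list[tuple[int, int]]]:
    """(names, elements, coords, bonds) of one ligand site near monomer A.

    Ring plane normal is +x; ring center at (2.2, -8, 0); tail extends -y.
    """
    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    center = np.array([2.2, -8.0, 0.0])
    for k, nm in enumerate(_RING_NAMES):
        ang = 2 * np.pi * k / 6
        coords.append(center + 1.4 * np.array([0.0, np.cos(ang), np.sin(ang)]))
        names.append(nm)
        elements.append(nm[0])
    # O3 on C3, O4 on C4: radially outward in the ring plane
    for nm, ring_k in (("O3", 2), ("O4", 3)):
        ring_pos = coords[ring_k]
        out = ring_pos - center
        out /= np.linalg.norm(out)
        coords.append(ring_pos + 1.4 * out)
        names.append(nm)
        elements.append("O")
    # phosphate-like tail hanging below the ring plane (-z), clear of the
    # O3/O4 hydroxyls and their donor partners
    p_pos = center + np.array([0.0, 0.0, -5.0])
    coords.append(p_pos)
    names.append("P")
    elements.append("P")
    # near-tetrahedral O-P-O angles (O..O about 2.45 A)
    for nm, direc in (("O1P", (0.0, 0.0, -1.0)),
                      ("O2P", (0.0, 0.943, 0.333)),
                      ("O3P", (0.0, -0.943, 0.333))):
        d = np.asarray(direc)
        coords.append(p_pos + 1.5 * d / np.linalg.norm(d))
        names.append(nm)
        elements.append("O")
    # optional dummy tail carbons to honour a larger requested atom count
    for extra in range(n_atoms - 12):
        coords.append(center + np.array([0.0, 0.0, 3.0 + 2.2 * (extra + 1)]))
        names.append(f"CT{extra + 1}")
        elements.append("C")
    bonds = [(k, (k + 1) % 6) for k in range(6)]          # ring cycle
    bonds += [(2, 6), (3, 7)]                              # C3-O3, C4-O4
    bonds += [(0, 8)]                                      # N1-P (toy linker)
    bonds += [(8, 9), (8, 10), (8, 11)]                    # P-O1P/O2P/O3P
    for extra in range(n_atoms - 12):
        bonds.append((5 if extra == 0 else 11 + extra, 12 + extra))
    return names, elements, np.array(coords), bonds


def build_toy_dimer(spec: SyntheticSpec) -> tuple[Topology, Frame]:
    """Construct the toy dimer topology and its reference frame.

    Monomer A carries, per residue, a Calpha (``CA``) and a sidechain dummy
    (``CB``); designated residues additionally carry hydrogen-bond donor
    oxygens (``OG``), a six-carbon stacking ring (``RC1..RC6``, planted
    coplanar with the ligand ring at 3.8 A separation), and the catalytic
    triad stand-ins ``NE2``/``OG1``/``ND1`` at 3.0 A pairwise spacing.
    Monomer B is the mirror image of A through the x = 0 plane; ligand sites
    L1/L2 mirror likewise.  The reference frame is sterically clean: every
    nonbonded pair is at least 2.0 A apart.
    """
    r = spec.residues_per_monomer
    names: list[str] = []
    elements: list[str] = []
    resnums: list[int] = []
    resnames: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []

    width = int(np.ceil(np.sqrt(r)))
    ca_index: dict[int, int] = {}
    for i in range(r):
        row, col = divmod(i, width)
        ca = np.array([6.0 + 4.0 * col, 4.0 * row, 0.0])
        ca_index[i + 1] = len(names)
        names.append("CA"); elements.append("C")
        resnums.append(i + 1); resnames.append("GLY")
        coords.append(ca)
        names.append("CB"); elements.append("C")
        resnums.append(i + 1); resnames.append("GLY")
        coords.append(ca + np.array([0.0, 0.0, 1.6]))
        n = len(names)
        bonds.append((n - 2, n - 1))          # CA-CB
        if i > 0:
            bonds.append((ca_index[i], n - 2))  # CA(i-1)-CA(i)

    # designated special residues (recorded in metadata)
    donor_res = list(range(r - 5, r + 1))[: spec.n_static_donors
                                          + spec.n_switching_donors]
    ring_res = r - 6
    triad_res = (r - 9, r - 8, r - 7)

    lig_names, lig_elements, lig_coords, lig_bonds = _ligand_template(
        spec.ligand_atoms_per_site)
    lig_center = lig_coords[:6].mean(axis=0)

    # hydrogen-bond donor oxygens: positioned at the formed pose, 2.9 A
    # radially outward from their designated ligand acceptor
    acceptors = _STATIC_ACCEPTORS[: spec.n_static_donors] + \
        _SWITCH_ACCEPTORS[: spec.n_switching_donors]
    donor_targets: list[tuple[int, str]] = []
    for res, acc in zip(donor_res, acceptors):
        a_pos = lig_coords[lig_names.index(acc)]
        u = a_pos - lig_center
        u /= np.linalg.norm(u)
        og = len(names)
        names.append("OG"); elements.append("O")
        resnums.append(res); resnames.append("GLY")
        coords.append(a_pos + 2.9 * u)
        bonds.append((ca_index[res], og))
        donor_targets.append((res, acc))

    # stacking ring parallel to the ligand ring, 3.8 A along the +x normal
    for k in range(6):
        ang = 2 * np.pi * k / 6
        pos = lig_center + np.array([3.8, 0.0, 0.0]) \
            + 1.4 * np.array([0.0, np.cos(ang), np.sin(ang)])
        idx = len(names)
        names.append(f"RC{k + 1}"); elements.append("C")
        resnums.append(ring_res); resnames.append("TRP")
        coords.append(pos)
        if k > 0:
            bonds.append((idx - 1, idx))
    bonds.append((len(names) - 6, len(names) - 1))        # close the ring
    bonds.append((ca_index[ring_res], len(names) - 6))

    # catalytic-triad stand-ins: colinear N/O/N at 3.0 A spacing
    triad_base = np.array([5.0, -14.0, 0.0])
    for nm, res, dz in (("NE2", triad_res[0], -3.0),
                        ("OG1", triad_res[1], 0.0),
                        ("ND1", triad_res[2], 3.0)):
        idx = len(names)
        names.append(nm); elements.append(nm[0])
        resnums.append(res); resnames.append("GLY")
        coords.append(triad_base + np.array([0.0, 0.0, dz]))
        bonds.append((ca_index[res], idx))

    n_mono = len(names)
    mono_coords = np.array(coords)

    # mirror monomer B through the x = 0 plane
    mirror = np.array([-1.0, 1.0, 1.0])
    full_names = names * 2
    full_elements = elements * 2
    full_resnums = resnums * 2
    full_resnames = resnames * 2
    full_groups = ["A"] * n_mono + ["B"] * n_mono
    full_coords = np.vstack([mono_coords, mono_coords * mirror])
    full_bonds = bonds + [(i + n_mono, j + n_mono) for i, j in bonds]

    # ligand sites: L1 near monomer A, L2 its mirror image near B
    n_lig = len(lig_names)
    lig1_offset = len(full_names)
    full_names += lig_names
    full_elements += lig_elements
    full_resnums += [500] * n_lig
    full_resnames += ["PLP"] * n_lig
    full_groups += ["L1"] * n_lig
    full_coords = np.vstack([full_coords, lig_coords])
    full_bonds += [(i + lig1_offset, j + lig1_offset) for i, j in lig_bonds]

    lig2_offset = len(full_names)
    full_names += lig_names
    full_elements += lig_elements
    full_resnums += [500] * n_lig
    full_resnames += ["PLP"] * n_lig
    full_groups += ["L2"] * n_lig
    full_coords = np.vstack([full_coords, lig_coords * mirror])
    full_bonds += [(i + lig2_offset, j + lig2_offset) for i, j in lig_bonds]

    top = Topology(
        names=full_names, elements=full_elements,
        resnums=np.array(full_resnums), resnames=full_resnames,
        groups=full_groups, bonds=full_bonds,
    )
    _parameterize(top, full_coords)

    core_lo = max(1, int(round(0.19 * r)))
    core_hi = max(core_lo + 1, int(round(0.73 * r)))
    top.metadata.update({
        "donor_residues": donor_res,
        "donor_targets": donor_targets,
        "static_donors": donor_res[: spec.n_static_donors],
        "switching_donors": donor_res[spec.n_static_donors:],
        "ring_residue": ring_res,
        "triad_residues": triad_res,
        "loop_range": spec.loop_range,
        "core_range": (core_lo, core_hi),
        "n_monomer_atoms": n_mono,
    })
    return top, Frame(full_coords)


def _parameterize(top: Topology, coords: np.ndarray) -> None:
    """Assign toy charges/LJ/GB/LCPO and equilibrium bond parameters."""
    n = top.n_atoms
    charges = np.zeros(n)
    for i in range(n):
        el = top.elements[i]
        nm = top.names[i]
        if top.groups[i] in ("L1", "L2"):
            charges[i] = {"N1": -0.55, "O3": -0.45, "O4": -0.45, "P": 1.35,
                          "O1P": -0.8, "O2P": -0.8, "O3P": -0.8}.get(
                nm, 0.12 if el == "C" else 0.0)
        else:
            charges[i] = {"CA": 0.10, "CB": -0.10, "OG": -0.40,
                          "NE2": -0.50, "OG1": -0.45, "ND1": -0.50}.get(nm, 0.0)
    # neutralize residues that carry a polar special atom via their CB
    for g in ("A", "B"):
        idx = top.group_indices(g)
        for res in set(int(top.resnums[i]) for i in idx):
            atoms = [i for i in idx if top.resnums[i] == res]
            net = charges[atoms].sum()
            cb = [i for i in atoms if top.names[i] == "CB"]
            if cb and abs(net) > 1e-12:
                charges[cb[0]] -= net
    # exact ligand net charge: mono-anionic cofactor (phosphate tail)
    for site in ("L1", "L2"):
        idx = top.group_indices(site)
        if idx.size:
            charges[idx] -= (charges[idx].sum() - (-1.0)) / idx.size

    top.charges = charges
    top.lj_eps = np.array([LJ_EPS[e] for e in top.elements])
    top.lj_rmin_half = np.array([LJ_RMIN_HALF[e] for e in top.elements])
    top.gb_radius = np.array([GB_RADIUS[e] for e in top.elements])
    top.gb_screen = np.array([GB_SCREEN[e] for e in top.elements])
    top.lcpo = np.array([LCPO[e] for e in top.elements])
    top.bond_terms = [
        BondTerm(i, j, BOND_K, float(np.linalg.norm(coords[i] - coords[j])))
        for i, j in top.bonds
    ]


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _rigid_body_modes(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3n, 6) of global translations and rotations."""
    n = coords.shape[0]
    center = coords.mean(axis=0)
    modes = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        modes.append(t.ravel())
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        rot = np.cross(omega, coords - center)
        modes.append(rot.ravel())
    basis = np.stack(modes, axis=1)
    q, _ = np.linalg.qr(basis)
    return q


def analysis_centers(top: Topology) -> np.ndarray:
    """The canonical coordinate-center set: all Calpha plus ligand C6."""
    ca = [i for i in range(top.n_atoms)
          if top.groups[i] in ("A", "B") and top.names[i] == "CA"]
    c6 = [i for i in range(top.n_atoms)
          if top.groups[i] in ("L1", "L2") and top.names[i] == "C6"]
    return np.array(sorted(ca + c6), dtype=int)


def interface_mode(top: Topology, reference: Frame) -> np.ndarray:
    """Interface-rotation mode: counter-rotation of the two monomer cores.

    Core atoms of monomer A rotate about a z axis through the core centroid;
    monomer B's core rotates oppositely.  The restriction of the mode to the
    canonical analysis centers (Calpha + ligand C6) is orthogonalized against
    that subset's six rigid-body modes — so a least-squares superposition of
    the centers cannot absorb the motion — and normalized to unit length,
    making the planted amplitude directly recoverable as a displacement in A.
    """
    lo, hi = top.metadata["core_range"]
    coords = reference.coords
    disp = np.zeros_like(coords)
    for g, sign in (("A", 1.0), ("B", -1.0)):
        idx = [i for i in top.group_indices(g)
               if lo <= top.resnums[i] <= hi]
        idx = np.asarray(idx, dtype=int)
        center = coords[idx].mean(axis=0)
        omega = np.array([0.0, 0.0, sign])
        disp[idx] = np.cross(omega, coords[idx] - center)
    # global rigid component first
    v = disp.ravel()
    rb = _rigid_body_modes(coords)
    v = (v - rb @ (rb.T @ v)).reshape(coords.shape)
    # then exact rigid-orthogonality on the analysis-center subset
    centers = analysis_centers(top)
    rb_s = _rigid_body_modes(coords[centers])
    vs = v[centers].ravel()
    vs = vs - rb_s @ (rb_s.T @ vs)
    v[centers] = vs.reshape(-1, 3)
    norm = np.linalg.norm(v[centers])
    if norm < 1e-12:
        raise ValueError("degenerate interface mode")
    return (v / norm).ravel()


def _label_rng(spec: SyntheticSpec, label: str) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed, zlib.crc32(label.encode("utf-8"))])


def generate_trajectory(
    top: Topology,
    reference: Frame,
    spec: SyntheticSpec,
    label: str,
) -> Trajectory:
    """Synthesize a trajectory with the planted structure of one system.

    Frames are built as reference + a(t) * interface mode + loop swing +
    hydrogen-bond donor toggling + iid Gaussian jitter, with
    a(t) ~ Normal(delta * pattern[label], amplitude SD).
    """
    if label not in spec.amplitude_means:
        raise KeyError(f"unknown system label {label!r}; declared systems: "
                       f"{sorted(spec.amplitude_means)}")
    rng = _label_rng(spec, label)
    f = spec.n_frames
    n = top.n_atoms
    coords = np.repeat(reference.coords[None], f, axis=0)

    mode = interface_mode(top, reference).reshape(n, 3)
    mean = spec.delta * spec.amplitude_means[label]
    amplitudes = rng.normal(mean, spec.amplitude_sd, size=f) \
        if spec.amplitude_sd > 0 else np.full(f, mean)
    coords += amplitudes[:, None, None] * mode[None]

    # loop "door" swing after the onset frame: coherent per-frame Gaussian
    # displacement along z with SD = loop_opening
    if spec.loop_opening > 0:
        lo, hi = spec.loop_range
        loop_idx = np.array([
            i for g in ("A", "B") for i in top.group_indices(g)
            if lo <= top.resnums[i] <= hi], dtype=int)
        onset = int(round(spec.loop_onset_fraction * f))
        swing = rng.normal(0.0, spec.loop_opening, size=f - onset)
        coords[onset:, loop_idx, 2] += swing[:, None]

    # two-state Markov hydrogen-bond donors
    switch_states: dict[str, np.ndarray] = {}
    p_formed = spec.k_on / (spec.k_on + spec.k_off) \
        if (spec.k_on + spec.k_off) > 0 else 1.0
    lig_for_group = {"A": "L1", "B": "L2"}
    for g in ("A", "B"):
        site = lig_for_group[g]
        lig_idx = top.group_indices(site)
        if lig_idx.size == 0:
            continue
        lig_center = reference.coords[lig_idx[:6]].mean(axis=0)
        for res, acc in top.metadata["donor_targets"]:
            if res not in top.metadata["switching_donors"]:
                continue
            og = top.index_of(g, res, "OG")
            acc_idx = lig_idx[[top.names[i] for i in lig_idx].index(acc)]
            a_pos = reference.coords[acc_idx]
            u = a_pos - lig_center
            u /= np.linalg.norm(u)
            states = np.empty(f, dtype=bool)
            states[0] = rng.random() < p_formed
            flips = rng.random(f)
            for t in range(1, f):
                if states[t - 1]:
                    states[t] = flips[t] >= spec.k_off
                else:
                    states[t] = flips[t] < spec.k_on
            dist = np.where(states, 2.9, 5.5)
            coords[:, og, :] = a_pos + dist[:, None] * u
            switch_states[f"{g}:{res}"] = states

    if spec.jitter_sd > 0:
        coords += rng.normal(0.0, spec.jitter_sd, size=coords.shape)

    times = spec.t0_ns + spec.dt_ns * np.arange(f)
    return Trajectory(
        coords, times, label,
        metadata={
            "planted_mode": mode,
            "planted_amplitude_mean": mean,
            "planted_amplitude_sd": spec.amplitude_sd,
            "planted_occupancy": p_formed,
            "switch_states": switch_states,
            "jitter_sd": spec.jitter_sd,
        },
    )
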