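"""Implicit-solvent molecular-mechanics energies and the EM/EE/EL/ET
decomposition of a homodimer with two cofactor sites.

Force field and solvent model
-----------------------------
* Bonded: harmonic bonds/angles (AMBER convention, E = k (x - x0)^2) and
  periodic torsions.
* Nonbonded: exact double loop, no cutoff, no periodicity.  Coulomb constant
  332.0637 kcal*A/(mol*e^2); Lennard-Jones in rmin/2 + epsilon form with
  Lorentz-Berthelot-style combination (rmin_ij = rmin_half_i + rmin_half_j,
  eps_ij = sqrt(eps_i eps_j)).  1-2 and 1-3 pairs excluded; 1-4 pairs scaled
  by 1/1.2 (Coulomb) and 1/2.0 (LJ).
* Polar solvation: generalized Born with OBC(II) effective radii —
  pairwise HCT descreening integral, tanh rescaling with alpha, beta, gamma =
  1.0, 0.8, 4.85 and a 0.09 A radius offset; the Still pair function
  f_GB = sqrt(r^2 + Ri Rj exp(-r^2 / (4 Ri Rj))); eps_in = 1, eps_out = 78.5.
* Nonpolar solvation: LCPO analytical solvent-accessible surface area
  (probe 1.4 A) times a surface tension of 0.005 kcal/(mol*A^2).

Decomposition
-------------
EM1/EM2 are the energies of each monomer extracted alone; EE is the
dimerization interaction (dimer minus monomers); EL per site is the cofactor
binding interaction (dimer+ligand minus dimer minus free ligand); ET is the
definitional sum EM + EE + EL.  Born radii are recomputed for each evaluation
context, so EE and EL carry the GB desolvation cross terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import Topology, Frame, Trajectory, extract_subsystem

# physical constants / model defaults
COULOMB_CONSTANT = 332.0637      # kcal*A/(mol*e^2)
EPS_IN = 1.0
EPS_OUT = 78.5
GB_OFFSET = 0.09                 # A
OBC_ALPHA, OBC_BETA, OBC_GAMMA = 1.0, 0.8, 4.85
SURFACE_TENSION = 0.005          # kcal/(mol*A^2)
PROBE_RADIUS = 1.4               # A
SCEE = 1.2                       # 1-4 Coulomb divisor
SCNB = 2.0                       # 1-4 LJ divisor

MIN_DISTANCE = 1e-6              # A; closer atoms are treated as overlapping


class EnergyError(ValueError):
    pass


def _require_parameters(top: Topology) -> None:
    if not top.is_parameterized:
        raise EnergyError("topology is not fully parameterized "
                          "(apply a parameter sidecar first)")


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    return d


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------

def bonded_energy(top: Topology, frame: Frame) -> float:
    """Sum of harmonic bond + angle + periodic torsion energies, kcal/mol."""
    _require_parameters(top)
    x = frame.coords
    e = 0.0
    for b in top.bond_terms:
        if b.k is None or b.r0 is None:
            raise EnergyError(
                f"missing bond parameters for atoms ({b.i}, {b.j})")
        r = np.linalg.norm(x[b.i] - x[b.j])
        e += b.k * (r - b.r0) ** 2
    for a in top.angle_terms:
        v1 = x[a.i] - x[a.j]
        v2 = x[a.k] - x[a.j]
        cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                         -1.0, 1.0)
        e += a.force_k * (np.arccos(cosang) - a.theta0) ** 2
    for t in top.torsion_terms:
        b1 = x[t.j] - x[t.i]
        b2 = x[t.k] - x[t.j]
        b3 = x[t.l] - x[t.k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = np.arctan2(m1 @ n2, n1 @ n2)
        e += t.height * (1.0 + np.cos(t.n * phi - t.phase))
    return float(e)


# ---------------------------------------------------------------------------
# Nonbonded pair scaling
# ---------------------------------------------------------------------------

def _nonbonded_scales(top: Topology) -> tuple[np.ndarray, np.ndarray]:
    """(coulomb_scale, lj_scale) n x n matrices encoding exclusions.

    1-2/1-3 pairs -> 0; 1-4 pairs -> 1/SCEE and 1/SCNB; everything else 1.
    Diagonal is 0.  Cached on the topology.
    """
    cached = top.metadata.get("_nb_scales")
    if cached is not None and cached[0].shape[0] == top.n_atoms:
        return cached
    n = top.n_atoms
    coul = np.ones((n, n))
    lj = np.ones((n, n))
    np.fill_diagonal(coul, 0.0)
    np.fill_diagonal(lj, 0.0)
    nb = top.neighbor_sets()
    for i in range(n):
        for j in nb[i]:                       # 1-2
            coul[i, j] = lj[i, j] = 0.0
            for k in nb[j]:                   # 1-3
                if k != i:
                    coul[i, k] = lj[i, k] = 0.0
    # 1-4: shortest bond path of length exactly 3 and not already excluded
    for i in range(n):
        for j in nb[i]:
            for k in nb[j]:
                if k == i:
                    continue
                for l in nb[k]:
                    if l in (i, j):
                        continue
                    if coul[i, l] == 1.0:
                        coul[i, l] = coul[l, i] = 1.0 / SCEE
                        lj[i, l] = lj[l, i] = 1.0 / SCNB
    top.metadata["_nb_scales"] = (coul, lj)
    return coul, lj


def coulomb_lj_energy(
    top: Topology,
    frame: Frame,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """Exact no-cutoff (Coulomb, LJ) energies in kcal/mol.

    With no groups: all intramolecular pairs under the exclusion/scaling
    rules.  With two disjoint groups: the cross-group interaction only.
    """
    _require_parameters(top)
    x = frame.coords
    q = top.charges
    eps = top.lj_eps
    rmin_half = top.lj_rmin_half
    coul_scale, lj_scale = _nonbonded_scales(top)

    d = _distance_matrix(x)
    np.fill_diagonal(d, np.inf)

    if group_a is None:
        mask = np.triu(np.ones_like(d, dtype=bool), k=1)
    else:
        ga = np.asarray(group_a, dtype=int)
        gb = np.asarray(group_b, dtype=int)
        if np.intersect1d(ga, gb).size:
            raise EnergyError("cross-group energy requires disjoint groups")
        mask = np.zeros_like(d, dtype=bool)
        mask[np.ix_(ga, gb)] = True

    if np.any(d[mask] < MIN_DISTANCE):
        raise EnergyError("overlapping atoms (r < 1e-6 A)")

    qq = np.outer(q, q)
    e_coul = float((COULOMB_CONSTANT * qq / d * coul_scale)[mask].sum())

    rmin = rmin_half[:, None] + rmin_half[None, :]
    eps_ij = np.sqrt(np.outer(eps, eps))
    ratio6 = (rmin / d) ** 6
    e_lj = float((eps_ij * (ratio6 ** 2 - 2.0 * ratio6) * lj_scale)[mask].sum())
    return e_coul, e_lj


# ---------------------------------------------------------------------------
# Generalized Born (OBC2)
# ---------------------------------------------------------------------------

def effective_born_radii(top: Topology, frame: Frame) -> np.ndarray:
    """Per-atom OBC effective Born radii, A.

    HCT pairwise descreening integral Psi with screened reduced radii,
    followed by the OBC tanh rescaling
    ``1/R_eff = 1/rho_tilde - tanh(a*Psi - b*Psi^2 + g*Psi^3) / rho``.
    An isolated atom (Psi = 0) has R_eff = rho - offset.
    """
    _require_parameters(top)
    rho = top.gb_radius - GB_OFFSET               # reduced radii rho_tilde
    if np.any(rho <= 0):
        raise EnergyError("intrinsic GB radius <= offset")
    screen = top.gb_screen if top.gb_screen is not None else \
        np.full(top.n_atoms, 0.8)
    sr = screen * rho                             # screened descreener radii

    x = frame.coords
    r = _distance_matrix(x)
    np.fill_diagonal(r, np.inf)

    rho_i = rho[:, None]
    sr_j = sr[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d_abs = np.abs(r - sr_j)
        u = r + sr_j
        l = np.maximum(rho_i, d_abs)
        term = 0.5 * (1.0 / l - 1.0 / u
                      + 0.25 * (r - sr_j ** 2 / r) * (1.0 / u ** 2 - 1.0 / l ** 2)
                      + 0.5 * np.log(l / u) / r)
        # sphere i fully inside the descreening sphere of j
        engulfed = sr_j - r > rho_i
        term = term + np.where(engulfed, 1.0 / rho_i - 1.0 / l, 0.0)
        # no contribution when sphere j is entirely inside i
        term = np.where(u <= rho_i, 0.0, term)
        term = np.where(np.isfinite(term), term, 0.0)
    integral = term.sum(axis=1)
    psi = integral * rho
    inner = OBC_ALPHA * psi - OBC_BETA * psi ** 2 + OBC_GAMMA * psi ** 3
    inv_reff = 1.0 / rho - np.tanh(inner) / top.gb_radius
    reff = 1.0 / inv_reff
    if not np.all(np.isfinite(reff)) or np.any(reff <= 0):
        raise EnergyError("non-finite or non-positive effective Born radius")
    return reff


def gb_polar_energy(
    top: Topology,
    frame: Frame,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
    radii: np.ndarray | None = None,
    eps_out: float = EPS_OUT,
) -> float:
    """Generalized Born polar solvation energy, kcal/mol.

    Total mode sums over all ordered pairs including self terms:
    ``-166.0319 (1/eps_in - 1/eps_out) sum_ij qi qj / f_GB``.  Cross mode
    (two disjoint groups) returns the inter-group part only (both pair
    orders).  ``radii`` defaults to the OBC radii of *this* topology/frame —
    pass radii of a larger context explicitly when decomposing.
    """
    _require_parameters(top)
    if radii is None:
        radii = effective_born_radii(top, frame)
    q = top.charges
    x = frame.coords
    r2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    rirj = np.outer(radii, radii)
    f = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
    pref = -(COULOMB_CONSTANT / 2.0) * (1.0 / EPS_IN - 1.0 / eps_out)
    pair = pref * np.outer(q, q) / f
    if group_a is None:
        return float(pair.sum())
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if np.intersect1d(ga, gb).size:
        raise EnergyError("cross-group energy requires disjoint groups")
    return float(2.0 * pair[np.ix_(ga, gb)].sum())


def born_self_energy(charge: float, radius: float,
                     eps_out: float = EPS_OUT) -> float:
    """Closed-form Born solvation energy of a single ion, kcal/mol."""
    return -(COULOMB_CONSTANT / 2.0) * (1.0 / EPS_IN - 1.0 / eps_out) \
        * charge ** 2 / radius


# ---------------------------------------------------------------------------
# LCPO surface area
# ---------------------------------------------------------------------------

def sasa_lcpo(top: Topology, frame: Frame) -> tuple[float, np.ndarray]:
    """LCPO solvent-accessible surface area: (total A^2, per-atom A^2).

    Linear combination of pairwise overlaps with per-atom coefficients
    P1..P4 and solvent-augmented radii R = r + probe:

    ``A_i = P1 S1 + P2 sum_j A_ij + P3 sum_{j,k} A_jk + P4 sum_j A_ij sum_k A_jk``

    where ``S1 = 4 pi R_i^2`` and ``A_ij`` is the area of sphere i buried in
    sphere j.  Negative per-atom areas are clamped to zero (standard LCPO
    behaviour for deeply buried atoms).
    """
    _require_parameters(top)
    radii = top.gb_radius + PROBE_RADIUS  # solvent-augmented spheres
    x = frame.coords
    n = top.n_atoms
    d = _distance_matrix(x)
    np.fill_diagonal(d, np.inf)

    ri = radii[:, None]
    rj = radii[None, :]
    overlap = d < ri + rj  # touching solvent-augmented spheres
    # buried area of sphere i inside sphere j, clamped to [0, full sphere]
    with np.errstate(invalid="ignore"):
        a_ij = 2.0 * np.pi * ri * (ri - d / 2.0 - (ri ** 2 - rj ** 2) / (2.0 * d))
    a_ij = np.where(overlap, np.clip(a_ij, 0.0, 4.0 * np.pi * ri ** 2), 0.0)

    p1, p2, p3, p4 = (top.lcpo[:, k] for k in range(4))
    s1 = 4.0 * np.pi * radii ** 2
    sum_aij = a_ij.sum(axis=1)

    per_atom = p1 * s1 + p2 * sum_aij
    # neighbour-of-neighbour terms
    for i in range(n):
        neigh = np.where(overlap[i])[0]
        if neigh.size == 0:
            continue
        ajk = 0.0
        aij_ajk = 0.0
        for j in neigh:
            jk = a_ij[j, neigh[(neigh != j)]].sum() if neigh.size > 1 else 0.0
            # restrict k to mutual neighbours of i
            ajk += jk
            aij_ajk += a_ij[i, j] * jk
        per_atom[i] += p3[i] * ajk + p4[i] * aij_ajk
    per_atom = np.clip(per_atom, 0.0, None)
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class EnergyRecord:
    """Term-level energy of one system in one frame, kcal/mol."""

    bonded: float
    coulomb: float
    lj: float
    gb: float
    sasa_area: float      # A^2
    nonpolar: float

    @property
    def total(self) -> float:
        return self.bonded + self.coulomb + self.lj + self.gb + self.nonpolar

    def as_dict(self) -> dict[str, float]:
        return {
            "bonded": self.bonded, "coulomb": self.coulomb, "lj": self.lj,
            "gb": self.gb, "sasa_area": self.sasa_area,
            "nonpolar": self.nonpolar, "total": self.total,
        }


def system_energy(top: Topology, frame: Frame) -> EnergyRecord:
    """All energy terms of one topology/frame evaluation context."""
    e_coul, e_lj = coulomb_lj_energy(top, frame)
    e_bonded = bonded_energy(top, frame)
    e_gb = gb_polar_energy(top, frame)
    area, _ = sasa_lcpo(top, frame)
    return EnergyRecord(e_bonded, e_coul, e_lj, e_gb, area,
                        SURFACE_TENSION * area)


@dataclass
class EnergyBreakdown:
    """Per-frame and summary EM/EE/EL/ET decomposition of one system."""

    per_frame: pd.DataFrame          # columns time_ns, EM1, EM2, EM, EE, ...
    label: str
    detail: dict = field(default_factory=dict)

    def summary(self, n_blocks: int = 5) -> pd.DataFrame:
        """Mean, per-frame population SD, and block-averaged SE per column."""
        cols = [c for c in self.per_frame.columns if c != "time_ns"]
        rows = []
        for c in cols:
            v = self.per_frame[c].to_numpy()
            blocks = np.array_split(v, min(n_blocks, len(v)))
            bmeans = np.array([b.mean() for b in blocks])
            rows.append({
                "term": c,
                "mean": v.mean(),
                "sd": v.std(),
                "block_se": bmeans.std(ddof=1) / np.sqrt(len(bmeans))
                if len(bmeans) > 1 else 0.0,
            })
        return pd.DataFrame(rows)

    def check_identity(self, tol: float = 1e-9) -> float:
        """Max per-frame |ET - EM - EE - EL|; raises above ``tol``."""
        pf = self.per_frame
        resid = (pf["ET"] - pf["EM"] - pf["EE"] - pf["EL"]).abs().max()
        if resid > tol:
            raise EnergyError(f"ET != EM + EE + EL (residual {resid:.3e})")
        return float(resid)


def _context_subsystems(top: Topology) -> dict[str, tuple[Topology, np.ndarray]]:
    """Evaluation contexts for the decomposition, with their atom indices."""
    a = top.group_indices("A")
    b = top.group_indices("B")
    l1 = top.group_indices("L1")
    l2 = top.group_indices("L2")
    dimer = np.concatenate([a, b])
    ctx = {
        "monomer_A": a,
        "monomer_B": b,
        "dimer": dimer,
        "ligand_1": l1,
        "ligand_2": l2,
        "dimer_L1": np.sort(np.concatenate([dimer, l1])),
        "dimer_L2": np.sort(np.concatenate([dimer, l2])),
    }
    out = {}
    for name, idx in ctx.items():
        if idx.size == 0:
            continue
        sub, _ = extract_subsystem(top, None, idx)
        out[name] = (sub, idx)
    return out


def decompose_em_ee_el(
    top: Topology,
    trajectory: Trajectory,
    last_ns: float | None = 800.0,
    stride_ns: float | None = 1.0,
) -> EnergyBreakdown:
    """EM/EE/EL/ET over the frame schedule (default: last 800 ns, 1/ns).

    Per frame (single-trajectory approximation — all contexts are extracted
    from the complex frame):

    * ``EMi``  = system energy of monomer i alone
    * ``EE``   = E(dimer, no ligands) - EM1 - EM2
    * ``EL_s`` = E(dimer + ligand s) - E(dimer) - E(ligand s alone)
    * ``ET``   = EM + EE + EL (definitional identity)
    """
    _require_parameters(top)
    win = trajectory.window(last_ns, stride_ns)
    contexts = _context_subsystems(top)
    has_l1 = "ligand_1" in contexts
    has_l2 = "ligand_2" in contexts

    records = []
    for k in range(win.n_frames):
        coords = win.coords[k]
        e: dict[str, float] = {}
        for name, (sub, idx) in contexts.items():
            e[name] = system_energy(sub, Frame(coords[idx])).total
        em1, em2 = e["monomer_A"], e["monomer_B"]
        em = em1 + em2
        ee = e["dimer"] - em1 - em2
        el1 = e["dimer_L1"] - e["dimer"] - e["ligand_1"] if has_l1 else 0.0
        el2 = e["dimer_L2"] - e["dimer"] - e["ligand_2"] if has_l2 else 0.0
        el = el1 + el2
        records.append({
            "time_ns": win.times[k],
            "EM1": em1, "EM2": em2, "EM": em,
            "EE": ee, "EL1": el1, "EL2": el2, "EL": el,
            "ET": em + ee + el,
        })
    return EnergyBreakdown(pd.DataFrame(records), win.label,
                           detail={"schedule": {"last_ns": last_ns,
                                                "stride_ns": stride_ns},
                                   "n_frames": win.n_frames})


# ---------------------------------------------------------------------------
# Per-residue pairwise decomposition
# ---------------------------------------------------------------------------

@dataclass
class PairwiseEnergyMatrix:
    """Per-residue cross-partition interaction energies, kcal/mol.

    ``partition`` is ``"interface"`` (monomer-monomer, the EE surface) or
    ``"ligand"`` (protein residues vs one cofactor site, the EL surface).
    ``mean``/``sd`` are over the frame schedule; ``per_frame_totals`` holds
    the summed cross energy of each frame for conservation checks.
    """

    residues: list[tuple[str, int]]      # (group, resnum) axis
    mean: np.ndarray
    sd: np.ndarray
    partition: str
    label: str
    per_frame_totals: np.ndarray = field(default_factory=lambda: np.array([]))

    def relative_to(self, reference: "PairwiseEnergyMatrix") -> "PairwiseEnergyMatrix":
        if reference.residues != self.residues:
            raise EnergyError("residue axes differ between systems")
        return PairwiseEnergyMatrix(
            self.residues, self.mean - reference.mean, self.sd,
            self.partition, f"{self.label}-vs-{reference.label}",
            self.per_frame_totals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": [g for g, _ in self.residues],
            "resnum": [r for _, r in self.residues],
            "mean_kcal": self.mean,
            "sd_kcal": self.sd,
            "system": self.label,
            "partition": self.partition,
        })


def _cross_pair_energy(sub: Topology, coords: np.ndarray,
                       ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Full (Coulomb + LJ + GB) cross energy per atom pair (ga x gb)."""
    q = sub.charges
    d = np.linalg.norm(coords[ga][:, None, :] - coords[gb][None, :, :], axis=2)
    if np.any(d < MIN_DISTANCE):
        raise EnergyError("overlapping atoms in pairwise decomposition")
    e_coul = COULOMB_CONSTANT * np.outer(q[ga], q[gb]) / d
    rmin = sub.lj_rmin_half[ga][:, None] + sub.lj_rmin_half[gb][None, :]
    eps_ij = np.sqrt(np.outer(sub.lj_eps[ga], sub.lj_eps[gb]))
    ratio6 = (rmin / d) ** 6
    e_lj = eps_ij * (ratio6 ** 2 - 2.0 * ratio6)
    radii = effective_born_radii(sub, Frame(coords))
    rirj = np.outer(radii[ga], radii[gb])
    f = np.sqrt(d ** 2 + rirj * np.exp(-(d ** 2) / (4.0 * rirj)))
    e_gb = -COULOMB_CONSTANT * (1.0 / EPS_IN - 1.0 / EPS_OUT) \
        * np.outer(q[ga], q[gb]) / f
    return e_coul + e_lj + e_gb


def pairwise_residue_decomposition(
    top: Topology,
    trajectory: Trajectory,
    partition: str = "interface",
    site: str = "L1",
    last_ns: float | None = 800.0,
    stride_ns: float | None = 1.0,
    reference: PairwiseEnergyMatrix | None = None,
) -> PairwiseEnergyMatrix:
    """Mean +- SD per-residue cross-partition interaction energies.

    ``partition="interface"``: cross monomer A/B pairs evaluated in the
    ligand-free dimer context; each pair energy is split half/half between
    its two residues.  ``partition="ligand"``: protein vs one cofactor site
    in the dimer+site context; each protein residue receives its full
    interaction with the cofactor.  The per-residue sums reproduce the total
    cross energy of each frame to machine precision.
    """
    _require_parameters(top)
    win = trajectory.window(last_ns, stride_ns)

    a = top.group_indices("A")
    b = top.group_indices("B")
    if partition == "interface":
        keep = np.sort(np.concatenate([a, b]))
    elif partition == "ligand":
        lig = top.group_indices(site)
        if lig.size == 0:
            raise EnergyError(f"no ligand atoms in site {site}")
        keep = np.sort(np.concatenate([a, b, lig]))
    else:
        raise EnergyError(f"unknown partition {partition!r}")

    sub, _ = extract_subsystem(top, None, keep)
    if partition == "interface":
        ga = sub.group_indices("A")
        gb = sub.group_indices("B")
    else:
        ga = np.sort(np.concatenate([sub.group_indices("A"),
                                     sub.group_indices("B")]))
        gb = sub.group_indices(site)
    if np.intersect1d(ga, gb).size:
        raise EnergyError("pairwise partitions overlap")

    res_keys = sorted({(sub.groups[i], int(sub.resnums[i])) for i in ga}
                      | ({(sub.groups[j], int(sub.resnums[j])) for j in gb}
                         if partition == "interface" else set()))
    res_index = {k: n for n, k in enumerate(res_keys)}
    row_res = np.array([res_index[(sub.groups[i], int(sub.resnums[i]))]
                        for i in ga])
    col_res = np.array([res_index.get((sub.groups[j], int(sub.resnums[j])), -1)
                        for j in gb])

    per_frame = np.zeros((win.n_frames, len(res_keys)))
    totals = np.zeros(win.n_frames)
    for k in range(win.n_frames):
        coords = win.coords[k][keep]
        e = _cross_pair_energy(sub, coords, ga, gb)
        totals[k] = e.sum()
        if partition == "interface":
            # half to each partner's residue
            row_sum = e.sum(axis=1)
            col_sum = e.sum(axis=0)
            np.add.at(per_frame[k], row_res, 0.5 * row_sum)
            np.add.at(per_frame[k], col_res, 0.5 * col_sum)
        else:
            np.add.at(per_frame[k], row_res, e.sum(axis=1))

    matrix = PairwiseEnergyMatrix(
        residues=res_keys,
        mean=per_frame.mean(axis=0),
        sd=per_frame.std(axis=0),
        partition=partition if partition == "interface" else f"ligand:{site}",
        label=win.label,
        per_frame_totals=totals,
    )
    if reference is not None:
        return matrix.relative_to(reference)
    return matrix


# ---------------------------------------------------------------------------
# Published reference table
# ---------------------------------------------------------------------------

def load_reference_energy_table() -> pd.DataFrame:
    """Reported MM-GB/SA effective energies (kcal/mol) for the hGOT1
    dimer-PLP systems (WT and the three clinical variants), with the
    definitional column ET = EM + EE + EL."""
    from importlib.resources import files

    path = files("dimertraj.data").joinpath("hgot1_energy_table.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
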