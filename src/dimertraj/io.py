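"""Readers/writers: single- and multi-model PDB, XYZ coordinate series,
and the TSV force-field parameter sidecar.

PDB files enter and leave through biotite; a light pre-scan of ATOM/HETATM
records provides line-numbered parse errors and rejects alternate locations
and insertion codes, which this package deliberately does not support.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .topology import (
    Frame,
    Topology,
    TopologyError,
    Trajectory,
    BondTerm,
    AngleTerm,
    TorsionTerm,
)

log = logging.getLogger(__name__)

#: HETATM residue names recognised as the cofactor/ligand
LIGAND_RESNAMES = {"PLP", "LIG"}

SIDECAR_COLUMNS = [
    "monomer", "resnum", "resname", "atomname", "charge_e", "lj_eps_kcal",
    "lj_rmin_half_A", "gb_radius_A", "lcpo_p1", "lcpo_p2", "lcpo_p3", "lcpo_p4",
]


class PDBParseError(ValueError):
    """Malformed or unsupported PDB content, with the offending line number."""


def _prescan_pdb(path: Path) -> None:
    """Line-level validation producing errors biotite cannot attribute."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}:{lineno}: truncated {rec} record")
            altloc = line[16]
            if altloc not in (" ", ""):
                raise PDBParseError(
                    f"{path}:{lineno}: alternate location {altloc!r} not supported")
            icode = line[26]
            if icode not in (" ", ""):
                raise PDBParseError(
                    f"{path}:{lineno}: insertion code {icode!r} not supported")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    f"{path}:{lineno}: unparseable coordinate/resnum field"
                ) from None


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG"):
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def _atoms_to_topology(atoms: struc.AtomArray) -> Topology:
    """Map a biotite atom array to a topology skeleton.

    Protein chains (ATOM records) must number exactly two; HETATM groups with
    a ligand residue name become ligand sites assigned by their chain label
    (first protein chain -> site L1, second -> site L2).
    """
    is_lig = np.isin(atoms.res_name, list(LIGAND_RESNAMES)) & atoms.hetero
    protein_chains = sorted(set(atoms.chain_id[~is_lig]))
    if len(protein_chains) != 2:
        raise TopologyError(
            f"expected exactly 2 protein chains, found {len(protein_chains)}: "
            f"{protein_chains}")
    chain2mono = {protein_chains[0]: "A", protein_chains[1]: "B"}

    groups: list[str] = []
    for k in range(atoms.array_length()):
        if is_lig[k]:
            groups.append("L1" if atoms.chain_id[k] == protein_chains[0] else "L2")
        else:
            groups.append(chain2mono[atoms.chain_id[k]])

    elements = [
        e.capitalize() if e else _guess_element(n)
        for e, n in zip(atoms.element, atoms.atom_name)
    ]
    top = Topology(
        names=list(atoms.atom_name),
        elements=elements,
        resnums=atoms.res_id.astype(int),
        resnames=list(atoms.res_name),
        groups=groups,
    )
    # duplicate atom within a residue -> error naming the residue
    seen: set[tuple[str, int, str]] = set()
    for i in range(top.n_atoms):
        key = top.atom_key(i)
        if key in seen:
            raise TopologyError(
                f"duplicate atom {key[2]!r} in residue "
                f"{top.resnames[i]}{key[1]} (group {key[0]})")
        seen.add(key)
    return top


def read_pdb(path: str | Path) -> tuple[Topology, Frame]:
    """Read a single-model PDB -> (topology skeleton, one frame).

    The skeleton carries identities only; force-field parameters come from
    :func:`read_parameter_sidecar`.
    """
    path = Path(path)
    _prescan_pdb(path)
    pdb = PDBFile.read(path)
    if pdb.get_model_count() != 1:
        raise PDBParseError(
            f"{path}: expected a single-model PDB, found "
            f"{pdb.get_model_count()} models (use read_trajectory)")
    atoms = pdb.get_structure(model=1)
    top = _atoms_to_topology(atoms)
    return top, Frame(atoms.coord)


def read_trajectory(
    path: str | Path,
    topology: Topology,
    label: str = "",
    times: tuple[float, float] | None = None,
) -> Trajectory:
    """Read a multi-model PDB or an XYZ series as a trajectory.

    ``times=(t0, dt)`` supplies time stamps in ns; XYZ comment lines of the
    form ``t= <value> ns`` are used when present and ``times`` is not given.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return _read_xyz(path, topology, label, times)
    _prescan_pdb(path)
    pdb = PDBFile.read(path)
    stack = pdb.get_structure()
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"{path}: frame atom count {coords.shape[1]} != topology "
            f"atom count {topology.n_atoms}")
    f = coords.shape[0]
    t0, dt = times if times is not None else (0.0, 1.0)
    return Trajectory(coords, t0 + dt * np.arange(f), label)


def _read_xyz(path: Path, topology: Topology, label: str,
              times: tuple[float, float] | None) -> Trajectory:
    frames: list[np.ndarray] = []
    stamps: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ValueError(f"{path}:{pos + 1}: expected atom count") from None
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        if natoms != topology.n_atoms:
            raise ValueError(
                f"{path}: frame {len(frames)} atom count {natoms} != "
                f"topology atom count {topology.n_atoms}")
        block = lines[pos + 2: pos + 2 + natoms]
        if len(block) < natoms:
            raise ValueError(f"{path}: truncated frame {len(frames)}")
        coords = np.array(
            [[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        tok = comment.replace("=", " = ").split()
        if "t" in tok:
            try:
                stamps.append(float(tok[tok.index("t") + 2]))
            except (IndexError, ValueError):
                pass
        pos += 2 + natoms
    coords = np.array(frames)
    if times is not None:
        t0, dt = times
        tvec = t0 + dt * np.arange(len(frames))
    elif len(stamps) == len(frames):
        tvec = np.array(stamps)
    else:
        tvec = np.arange(len(frames), dtype=float)
    return Trajectory(coords, tvec, label)


def _topology_to_atoms(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32)
    chain = {"A": "A", "B": "B", "L1": "A", "L2": "B"}
    for i in range(n):
        atoms.chain_id[i] = chain[topology.groups[i]]
        atoms.res_id[i] = topology.resnums[i]
        atoms.res_name[i] = topology.resnames[i]
        atoms.atom_name[i] = topology.names[i]
        atoms.element[i] = topology.elements[i].upper()
        atoms.hetero[i] = topology.groups[i] in ("L1", "L2")
    return atoms


def write_pdb(topology: Topology, frames: Frame | Trajectory,
              path: str | Path) -> None:
    """Write a single frame or a whole trajectory as (multi-model) PDB."""
    if isinstance(frames, Frame):
        stack = _topology_to_atoms(topology, frames.coords)
    else:
        arrays = [_topology_to_atoms(topology, frames.coords[k])
                  for k in range(frames.n_frames)]
        stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(Path(path))


def write_xyz(topology: Topology, trajectory: Trajectory,
              path: str | Path) -> None:
    """Write an XYZ coordinate series; comment lines carry ``t= <ns> ns``."""
    with open(path, "w") as fh:
        for k in range(trajectory.n_frames):
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"t= {trajectory.times[k]:.6f} ns\n")
            for el, xyz in zip(topology.elements, trajectory.coords[k]):
                fh.write(f"{el:2s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")


# ---------------------------------------------------------------------------
# Parameter sidecar
# ---------------------------------------------------------------------------

def read_parameter_sidecar(path: str | Path, topology: Topology) -> Topology:
    """Apply a flat TSV parameter table to a topology skeleton.

    Atom rows are keyed by (monomer/site, residue number, atom name) and carry
    charge, LJ, intrinsic GB radius, optional GB screening factor, and the four
    LCPO coefficients.  Optional rows:

    * ``BOND <g1> <r1> <n1> <g2> <r2> <n2> <k> <r0>`` — harmonic bond term
    * ``ANGLE`` / ``DIHEDRAL`` — analogous, with their own parameter tails
    * ``NETCHARGE <group> <q>`` — declared net charge; a mismatch beyond
      1e-3 e logs a warning.

    Every topology atom must be covered; unparameterized atoms raise an error
    listing them.
    """
    path = Path(path)
    n = topology.n_atoms
    charges = np.full(n, np.nan)
    lj_eps = np.full(n, np.nan)
    lj_rmin = np.full(n, np.nan)
    gb_r = np.full(n, np.nan)
    gb_s = np.full(n, 0.8)
    lcpo = np.full((n, 4), np.nan)
    bond_params: dict[frozenset[int], tuple[float, float]] = {}
    angle_terms: list[AngleTerm] = []
    torsion_terms: list[TorsionTerm] = []
    declared_net: dict[str, float] = {}

    key_index = {topology.atom_key(i): i for i in range(n)}

    def _resolve(group: str, resnum: str, name: str, lineno: int) -> int:
        key = (group, int(resnum), name)
        if key not in key_index:
            raise TopologyError(f"{path}:{lineno}: sidecar references unknown "
                                f"atom {key}")
        return key_index[key]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split("\t") if "\t" in line else line.split()
            if tok[0] == "BOND":
                i = _resolve(tok[1], tok[2], tok[3], lineno)
                j = _resolve(tok[4], tok[5], tok[6], lineno)
                bond_params[frozenset((i, j))] = (float(tok[7]), float(tok[8]))
            elif tok[0] == "ANGLE":
                i = _resolve(tok[1], tok[2], tok[3], lineno)
                j = _resolve(tok[4], tok[5], tok[6], lineno)
                k = _resolve(tok[7], tok[8], tok[9], lineno)
                angle_terms.append(AngleTerm(i, j, k, float(tok[10]),
                                             float(tok[11])))
            elif tok[0] == "DIHEDRAL":
                idx = [_resolve(tok[3 * m + 1], tok[3 * m + 2], tok[3 * m + 3],
                                lineno) for m in range(4)]
                torsion_terms.append(TorsionTerm(*idx, float(tok[13]),
                                                 int(tok[14]), float(tok[15])))
            elif tok[0] == "NETCHARGE":
                declared_net[tok[1]] = float(tok[2])
            else:
                if tok[0] == "monomer":  # header row
                    continue
                if len(tok) < 12:
                    raise TopologyError(
                        f"{path}:{lineno}: atom row needs 12 columns")
                key = (tok[0], int(tok[1]), tok[3])
                if key not in key_index:
                    # resname in column 3 is informative only
                    raise TopologyError(
                        f"{path}:{lineno}: sidecar references unknown atom {key}")
                i = key_index[key]
                charges[i] = float(tok[4])
                lj_eps[i] = float(tok[5])
                lj_rmin[i] = float(tok[6])
                gb_r[i] = float(tok[7])
                lcpo[i] = [float(x) for x in tok[8:12]]
                if len(tok) >= 13:
                    gb_s[i] = float(tok[12])

    missing = [topology.atom_key(i) for i in range(n) if np.isnan(charges[i])]
    if missing:
        raise TopologyError(
            f"sidecar {path} leaves {len(missing)} atom(s) unparameterized: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    if np.any(gb_r <= 0):
        bad = [topology.atom_key(i) for i in np.where(gb_r <= 0)[0]]
        raise TopologyError(f"non-positive GB radius for atoms {bad}")

    for group, declared in declared_net.items():
        idx = topology.group_indices(group)
        total = float(charges[idx].sum())
        if abs(total - declared) > 1e-3:
            log.warning(
                "group %s net charge %.4f e differs from declared %.4f e",
                group, total, declared)

    # BOND rows both parameterize existing bonds and add missing ones
    # (a PDB-derived skeleton carries no connectivity of its own)
    existing = {frozenset(b) for b in topology.bonds}
    for pair in bond_params:
        if pair not in existing:
            i, j = sorted(pair)
            if {topology.groups[i], topology.groups[j]} == {"A", "B"}:
                raise TopologyError(
                    f"sidecar bond ({i}, {j}) crosses the monomer A/B boundary")
            topology.bonds.append((i, j))
    bond_terms = []
    for i, j in topology.bonds:
        params = bond_params.get(frozenset((i, j)))
        if params is None:
            bond_terms.append(BondTerm(i, j))
        else:
            bond_terms.append(BondTerm(i, j, params[0], params[1]))

    topology.charges = charges
    topology.lj_eps = lj_eps
    topology.lj_rmin_half = lj_rmin
    topology.gb_radius = gb_r
    topology.gb_screen = gb_s
    topology.lcpo = lcpo
    topology.bond_terms = bond_terms
    topology.angle_terms = angle_terms
    topology.torsion_terms = torsion_terms
    topology.validate()
    return topology


def write_parameter_sidecar(topology: Topology, path: str | Path) -> None:
    """Inverse of :func:`read_parameter_sidecar` for a parameterized topology."""
    if not topology.is_parameterized:
        raise TopologyError("cannot write sidecar for unparameterized topology")
    with open(path, "w") as fh:
        fh.write("\t".join(SIDECAR_COLUMNS + ["gb_screen"]) + "\n")
        for i in range(topology.n_atoms):
            g, rn, name = topology.atom_key(i)
            row = [
                g, str(rn), topology.resnames[i], name,
                f"{topology.charges[i]:.6f}",
                f"{topology.lj_eps[i]:.6f}",
                f"{topology.lj_rmin_half[i]:.6f}",
                f"{topology.gb_radius[i]:.6f}",
                *(f"{v:.8f}" for v in topology.lcpo[i]),
                f"{topology.gb_screen[i]:.4f}",
            ]
            fh.write("\t".join(row) + "\n")
        for t in topology.bond_terms:
            if t.k is None:
                continue
            gi, ri, ni = topology.atom_key(t.i)
            gj, rj, nj = topology.atom_key(t.j)
            fh.write(f"BOND\t{gi}\t{ri}\t{ni}\t{gj}\t{rj}\t{nj}"
                     f"\t{t.k:.4f}\t{t.r0:.6f}\n")
        for a in topology.angle_terms:
            keys = [topology.atom_key(x) for x in (a.i, a.j, a.k)]
            flat = "\t".join(f"{g}\t{r}\t{n}" for g, r, n in keys)
            fh.write(f"ANGLE\t{flat}\t{a.force_k:.4f}\t{a.theta0:.6f}\n")
        for d in topology.torsion_terms:
            keys = [topology.atom_key(x) for x in (d.i, d.j, d.k, d.l)]
            flat = "\t".join(f"{g}\t{r}\t{n}" for g, r, n in keys)
            fh.write(f"DIHEDRAL\t{flat}\t{d.height:.4f}\t{d.n}\t{d.phase:.6f}\n")
        for group in ("A", "B", "L1", "L2"):
            idx = topology.group_indices(group)
            if idx.size:
                fh.write(f"NETCHARGE\t{group}\t{topology.charges[idx].sum():.6f}\n")
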