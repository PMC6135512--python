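"""Core domain types: topology, frames, trajectories, atom selection.

The package models a two-monomer (homodimer) protein with up to two bound
ligand copies, one per active site.  Every atom belongs to exactly one of
four groups: monomer ``A``, monomer ``B``, ligand site ``L1`` or ligand
site ``L2``.  Residue numbers follow author/PDB numbering (1-based) and all
residue ranges are closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

#: valid atom group labels: the two monomers and the two ligand binding sites
GROUPS = ("A", "B", "L1", "L2")
MONOMERS = ("A", "B")
LIGAND_SITES = ("L1", "L2")


class TopologyError(ValueError):
    """Raised when a topology violates a structural invariant."""


@dataclass
class BondTerm:
    """Harmonic bond, AMBER convention E = k (r - r0)^2."""

    i: int
    j: int
    k: float | None = None   # kcal/mol/A^2
    r0: float | None = None  # A


@dataclass
class AngleTerm:
    """Harmonic angle, E = force_k (theta - theta0)^2 (theta in radians)."""

    i: int
    j: int
    k: int
    force_k: float  # kcal/mol/rad^2
    theta0: float   # radians


@dataclass
class TorsionTerm:
    """Periodic torsion, E = height * (1 + cos(n*phi - phase))."""

    i: int
    j: int
    k: int
    l: int
    height: float  # kcal/mol
    n: int
    phase: float   # radians


@dataclass
class Topology:
    """Atom identities, group partition, bonds and force-field parameters.

    Force-field parameters (charges, LJ, GB radii, LCPO) are ``None`` until a
    parameter sidecar is applied; a topology straight from a PDB file is a
    "skeleton".
    """

    names: list[str]
    elements: list[str]
    resnums: np.ndarray          # int, author numbering, per atom
    resnames: list[str]
    groups: list[str]            # per atom, one of GROUPS
    bonds: list[tuple[int, int]] = field(default_factory=list)

    charges: np.ndarray | None = None        # e
    lj_eps: np.ndarray | None = None         # kcal/mol
    lj_rmin_half: np.ndarray | None = None   # A
    gb_radius: np.ndarray | None = None      # A (intrinsic)
    gb_screen: np.ndarray | None = None      # dimensionless HCT screening
    lcpo: np.ndarray | None = None           # (n, 4) LCPO P1..P4

    bond_terms: list[BondTerm] = field(default_factory=list)
    angle_terms: list[AngleTerm] = field(default_factory=list)
    torsion_terms: list[TorsionTerm] = field(default_factory=list)

    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        n = len(self.names)
        for attr in ("elements", "resnames", "groups"):
            if len(getattr(self, attr)) != n:
                raise TopologyError(f"{attr} length != number of atoms ({n})")
        if self.resnums.shape != (n,):
            raise TopologyError("resnums length != number of atoms")
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise TopologyError(f"unknown atom groups {bad}; expected one of {GROUPS}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"invalid bond ({i}, {j})")
            gi, gj = self.groups[i], self.groups[j]
            if {gi, gj} == {"A", "B"}:
                raise TopologyError(
                    f"bond ({i}, {j}) crosses the monomer A/B boundary"
                )

    # -- basic queries -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def group_indices(self, group: str) -> np.ndarray:
        """Sorted atom indices belonging to one group (``A``/``B``/``L1``/``L2``)."""
        if group not in GROUPS:
            raise TopologyError(f"unknown group {group!r}")
        return np.array(
            [i for i, g in enumerate(self.groups) if g == group], dtype=int
        )

    def atom_key(self, i: int) -> tuple[str, int, str]:
        """Stable identity of atom ``i``: (group, residue number, atom name)."""
        return (self.groups[i], int(self.resnums[i]), self.names[i])

    def index_of(self, group: str, resnum: int, name: str) -> int:
        """Index of the atom with the given (group, resnum, name) key."""
        key = (group, resnum, name)
        try:
            return self._key_index()[key]
        except KeyError:
            raise TopologyError(f"no atom with key {key}") from None

    def _key_index(self) -> dict[tuple[str, int, str], int]:
        cache = self.metadata.get("_key_index")
        if cache is None or len(cache) != self.n_atoms:
            cache = {self.atom_key(i): i for i in range(self.n_atoms)}
            if len(cache) != self.n_atoms:
                raise TopologyError("duplicate (group, resnum, name) atom keys")
            self.metadata["_key_index"] = cache
        return cache

    def residues(self, group: str) -> list[tuple[int, str]]:
        """Ordered unique (resnum, resname) pairs of a group."""
        seen: dict[int, str] = {}
        for i in self.group_indices(group):
            seen.setdefault(int(self.resnums[i]), self.resnames[i])
        return sorted(seen.items())

    def monomer_ranges(self) -> dict[str, tuple[int, int]]:
        """Closed residue-number interval covered by each monomer."""
        out = {}
        for m in MONOMERS:
            idx = self.group_indices(m)
            if idx.size:
                rn = self.resnums[idx]
                out[m] = (int(rn.min()), int(rn.max()))
        return out

    @property
    def is_parameterized(self) -> bool:
        return all(
            x is not None
            for x in (self.charges, self.lj_eps, self.lj_rmin_half,
                      self.gb_radius, self.lcpo)
        )

    def validate(self) -> None:
        """Check structural invariants; raise :class:`TopologyError` on violation."""
        counts = sum(self.group_indices(g).size for g in GROUPS)
        if counts != self.n_atoms:
            raise TopologyError("group partition does not cover all atoms")
        if self.charges is not None and not np.all(np.isfinite(self.charges)):
            raise TopologyError("non-finite partial charges")
        if self.gb_radius is not None and np.any(self.gb_radius <= 0):
            raise TopologyError("intrinsic GB radii must be > 0")

    # -- neighbour/exclusion machinery used by energetics ------------------

    def neighbor_sets(self) -> list[set[int]]:
        nb: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            nb[i].add(j)
            nb[j].add(i)
        return nb

    def bonded_hydrogens(self, i: int) -> list[int]:
        """Indices of hydrogen atoms bonded to atom ``i``."""
        return [j for j in self.neighbor_sets()[i] if self.elements[j] == "H"]


@dataclass
class Frame:
    """A single set of per-atom coordinates in Angstrom."""

    coords: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered coordinate frames with time stamps (ns) and a system label."""

    coords: np.ndarray       # (n_frames, n_atoms, 3), A
    times: np.ndarray        # ns, strictly increasing
    label: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coordinates must have shape (F, n, 3)")
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("len(times) != number of frames")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i])

    def window(self, last_ns: float | None = None,
               stride_ns: float | None = None) -> "Trajectory":
        """Sub-trajectory covering the last ``last_ns`` ns at ``stride_ns`` spacing.

        With ``last_ns=800`` on a 0..999 ns run this keeps the 800 frames with
        t >= t_end - 800; ``stride_ns`` keeps every frame whose offset from the
        window start is a multiple of the stride (to 1e-9 ns).
        """
        span = float(self.times[-1] - self.times[0])
        step = float(np.median(np.diff(self.times))) if self.n_frames > 1 else 0.0
        if last_ns is not None and last_ns > span + step + 1e-9:
            raise ValueError(
                f"schedule window ({last_ns} ns) extends outside the "
                f"trajectory (span {span} ns)")
        if stride_ns is not None and self.n_frames > 1 and stride_ns > span:
            raise ValueError(
                f"schedule stride ({stride_ns} ns) exceeds the trajectory "
                f"span ({span} ns)")
        mask = np.ones(self.n_frames, dtype=bool)
        if last_ns is not None:
            mask &= self.times >= self.times[-1] - last_ns + 1e-9
        if stride_ns is not None and stride_ns > 0:
            t0 = self.times[mask][0] if mask.any() else 0.0
            rel = (self.times - t0) / stride_ns
            mask &= np.abs(rel - np.round(rel)) < 1e-6
        if not mask.any():
            raise ValueError("frame schedule selects no frames of this trajectory")
        return Trajectory(self.coords[mask], self.times[mask], self.label,
                          dict(self.metadata))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionTerm:
    """One conjunctive constraint set; ``None`` fields are unconstrained."""

    groups: tuple[str, ...] | None = None
    resnum_range: tuple[int, int] | None = None  # closed interval
    resname: str | None = None
    name: str | None = None


@dataclass(frozen=True)
class SelectionSpec:
    """Union of :class:`SelectionTerm` constraints.

    Evaluation on a fixed topology is deterministic and returns a sorted,
    duplicate-free index array.
    """

    terms: tuple[SelectionTerm, ...]

    @staticmethod
    def ca_plus_ligand_atom(res_lo: int, res_hi: int,
                            ligand_atom: str = "C6") -> "SelectionSpec":
        """Cα of residues [res_lo, res_hi] on both monomers plus one named
        ligand atom per binding site — the essential-dynamics center set."""
        return SelectionSpec(terms=(
            SelectionTerm(groups=("A", "B"), resnum_range=(res_lo, res_hi),
                          name="CA"),
            SelectionTerm(groups=("L1", "L2"), name=ligand_atom),
        ))


def select(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Evaluate a selection on a topology -> sorted unique atom indices.

    An atom-name constraint matching nothing anywhere in the topology logs a
    warning and its term contributes no atoms (per-term, not an error).
    """
    hits: set[int] = set()
    all_names = set(topology.names)
    for term in spec.terms:
        if term.name is not None and term.name not in all_names:
            log.warning("selection term names unknown atom %r; term ignored",
                        term.name)
            continue
        for i in range(topology.n_atoms):
            if term.groups is not None and topology.groups[i] not in term.groups:
                continue
            if term.resnum_range is not None:
                lo, hi = term.resnum_range
                if not (lo <= topology.resnums[i] <= hi):
                    continue
            if term.resname is not None and topology.resnames[i] != term.resname:
                continue
            if term.name is not None and topology.names[i] != term.name:
                continue
            hits.add(i)
    return np.array(sorted(hits), dtype=int)


def extract_subsystem(
    topology: Topology,
    trajectory: Trajectory | Frame | None,
    indices: Sequence[int] | np.ndarray,
) -> tuple[Topology, Trajectory | Frame | None]:
    """Restrict topology (and optionally coordinates) to an atom subset.

    Parameters are kept, atoms renumbered contiguously, and any bond or bonded
    term with an endpoint outside the subset is dropped.
    """
    idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= topology.n_atoms):
        raise IndexError("subsystem index out of range")
    old2new = {int(o): n for n, o in enumerate(idx)}

    def _sub(arr):
        return None if arr is None else np.asarray(arr)[idx]

    sub = Topology(
        names=[topology.names[i] for i in idx],
        elements=[topology.elements[i] for i in idx],
        resnums=topology.resnums[idx],
        resnames=[topology.resnames[i] for i in idx],
        groups=[topology.groups[i] for i in idx],
        bonds=[(old2new[i], old2new[j]) for i, j in topology.bonds
               if i in old2new and j in old2new],
        charges=_sub(topology.charges),
        lj_eps=_sub(topology.lj_eps),
        lj_rmin_half=_sub(topology.lj_rmin_half),
        gb_radius=_sub(topology.gb_radius),
        gb_screen=_sub(topology.gb_screen),
        lcpo=None if topology.lcpo is None else topology.lcpo[idx],
        bond_terms=[BondTerm(old2new[t.i], old2new[t.j], t.k, t.r0)
                    for t in topology.bond_terms
                    if t.i in old2new and t.j in old2new],
        angle_terms=[AngleTerm(old2new[t.i], old2new[t.j], old2new[t.k],
                               t.force_k, t.theta0)
                     for t in topology.angle_terms
                     if all(x in old2new for x in (t.i, t.j, t.k))],
        torsion_terms=[TorsionTerm(old2new[t.i], old2new[t.j], old2new[t.k],
                                   old2new[t.l], t.height, t.n, t.phase)
                       for t in topology.torsion_terms
                       if all(x in old2new for x in (t.i, t.j, t.k, t.l))],
    )
    if trajectory is None:
        return sub, None
    if isinstance(trajectory, Frame):
        return sub, Frame(trajectory.coords[idx])
    return sub, Trajectory(trajectory.coords[:, idx, :], trajectory.times,
                           trajectory.label, dict(trajectory.metadata))
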