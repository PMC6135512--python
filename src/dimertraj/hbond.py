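"""Geometric hydrogen-bond detection, occupancies, and network comparison.

A bond's identity is the (donor heavy atom, acceptor heavy atom) pair;
multiple hydrogens on one donor count once per frame, so occupancies never
exceed 1.  Default criteria: donor-acceptor heavy-atom distance <= 3.5 A and
D-H-A angle >= 135 deg; topologies without explicit hydrogens use the
heavy-atom-only fallback (distance criterion alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

import numpy as np
import pandas as pd

from .topology import Topology, Frame, Trajectory

DONOR_ACCEPTOR_ELEMENTS = ("N", "O")


@dataclass(frozen=True)
class HBondCriteria:
    distance_cutoff: float = 3.5   # A, donor-acceptor heavy atoms
    angle_min_deg: float = 135.0   # D-H-A
    require_hydrogen: bool = False

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not (0 < self.angle_min_deg <= 180):
            raise ValueError("angle minimum must lie in (0, 180]")


def _donors_acceptors(
    topology: Topology, criteria: HBondCriteria
) -> tuple[list[tuple[int, list[int]]], list[int], bool]:
    """Donor (heavy atom, attached hydrogens) list, acceptor list, and
    whether hydrogen geometry is available."""
    has_h = any(e == "H" for e in topology.elements)
    if criteria.require_hydrogen and not has_h:
        raise ValueError(
            "hydrogen-required criteria on a hydrogen-free topology; "
            "use heavy-atom-only mode (require_hydrogen=False)")
    nb = topology.neighbor_sets()
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    for i, el in enumerate(topology.elements):
        if el not in DONOR_ACCEPTOR_ELEMENTS:
            continue
        acceptors.append(i)
        hyds = [j for j in nb[i] if topology.elements[j] == "H"]
        if has_h:
            if hyds:
                donors.append((i, sorted(hyds)))
        else:
            donors.append((i, []))
    return donors, acceptors, has_h


def _excluded(topology: Topology) -> set[frozenset[int]]:
    """Pairs never considered: bonded (1-2) and angle (1-3) neighbours."""
    nb = topology.neighbor_sets()
    out: set[frozenset[int]] = set()
    for i, j in topology.bonds:
        out.add(frozenset((i, j)))
        for k in nb[j]:
            if k != i:
                out.add(frozenset((i, k)))
        for k in nb[i]:
            if k != j:
                out.add(frozenset((j, k)))
    return out


def candidate_pairs(
    topology: Topology,
    criteria: HBondCriteria,
    restriction: str | Callable[[int, int], bool] | None = None,
) -> list[tuple[int, list[int], int]]:
    """All (donor, hydrogens, acceptor) combinations worth measuring.

    ``restriction``:
      * ``None`` — all donor/acceptor pairs in different residues,
      * ``"ligand-protein"`` — exactly one partner in a ligand group (the
        "cofactor-coupled" network restriction),
      * a callable ``f(donor_index, acceptor_index) -> bool``.
    """
    donors, acceptors, _ = _donors_acceptors(topology, criteria)
    excluded = _excluded(topology)
    if restriction == "ligand-protein":
        def keep(d: int, a: int) -> bool:
            gd, ga = topology.groups[d], topology.groups[a]
            return (gd.startswith("L")) != (ga.startswith("L"))
    elif callable(restriction):
        keep = restriction
    else:
        def keep(d: int, a: int) -> bool:
            return True
    has_h = any(e == "H" for e in topology.elements)
    out = []
    for d, hyds in donors:
        dres = (topology.groups[d], int(topology.resnums[d]))
        for a in acceptors:
            if a == d:
                continue
            # heavy-atom mode cannot distinguish donor from acceptor:
            # emit each unordered pair once
            if not has_h and a < d:
                continue
            if (topology.groups[a], int(topology.resnums[a])) == dres:
                continue
            if frozenset((d, a)) in excluded:
                continue
            if keep(d, a):
                out.append((d, hyds, a))
    return out


def _formed_matrix(
    coords: np.ndarray,
    pairs: list[tuple[int, list[int], int]],
    criteria: HBondCriteria,
    use_hydrogens: bool,
) -> np.ndarray:
    """(F, n_pairs) boolean matrix of per-frame bond formation."""
    d_idx = np.array([p[0] for p in pairs], dtype=int)
    a_idx = np.array([p[2] for p in pairs], dtype=int)
    dist = np.linalg.norm(coords[:, d_idx, :] - coords[:, a_idx, :], axis=2)
    formed = dist <= criteria.distance_cutoff
    if use_hydrogens:
        cos_max = np.cos(np.radians(criteria.angle_min_deg))
        for col, (d, hyds, a) in enumerate(pairs):
            if not hyds:
                formed[:, col] = False
                continue
            ok = np.zeros(coords.shape[0], dtype=bool)
            for h in hyds:
                hd = coords[:, d, :] - coords[:, h, :]
                ha = coords[:, a, :] - coords[:, h, :]
                cosang = (hd * ha).sum(axis=1) / (
                    np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1))
                # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
                ok |= cosang <= cos_max
            formed[:, col] &= ok
    return formed


def find_hbonds(
    topology: Topology,
    frame: Frame,
    criteria: HBondCriteria = HBondCriteria(),
    restriction: str | Callable[[int, int], bool] | None = None,
) -> list[tuple[int, int | None, int]]:
    """Hydrogen bonds present in one frame, sorted by (donor, acceptor).

    Returns ``(donor, hydrogen-or-None, acceptor)`` triples; in heavy-atom
    mode the hydrogen slot is ``None``.
    """
    pairs = candidate_pairs(topology, criteria, restriction)
    if not pairs:
        return []
    _, _, has_h = _donors_acceptors(topology, criteria)
    formed = _formed_matrix(frame.coords[None], pairs, criteria, has_h)[0]
    out = []
    for col, (d, hyds, a) in enumerate(pairs):
        if formed[col]:
            out.append((d, hyds[0] if hyds else None, a))
    return sorted(out, key=lambda t: (t[0], t[2]))


def occupancy_table(
    trajectory: Trajectory,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    restriction: str | Callable[[int, int], bool] | None = None,
) -> pd.DataFrame:
    """Per-bond occupancy (fraction of frames formed) over a trajectory.

    One row per bond observed in at least one frame; occupancy is the exact
    rational ``formed / total`` evaluated in floating point, with the integer
    counts kept alongside.
    """
    if trajectory.n_frames == 0:
        raise ValueError("occupancy over zero frames is undefined")
    pairs = candidate_pairs(topology, criteria, restriction)
    _, _, has_h = _donors_acceptors(topology, criteria)
    rows = []
    if pairs:
        formed = _formed_matrix(trajectory.coords, pairs, criteria, has_h)
        counts = formed.sum(axis=0)
        total = trajectory.n_frames
        for col, (d, _, a) in enumerate(pairs):
            if counts[col] == 0:
                continue
            gd, rd, nd = topology.atom_key(d)
            ga, ra, na = topology.atom_key(a)
            rows.append({
                "donor_index": d,
                "acceptor_index": a,
                "donor": f"{gd}:{topology.resnames[d]}{rd}:{nd}",
                "acceptor": f"{ga}:{topology.resnames[a]}{ra}:{na}",
                "formed": int(counts[col]),
                "total": int(total),
                "occupancy": float(Fraction(int(counts[col]), int(total))),
                "system": trajectory.label,
            })
    df = pd.DataFrame(rows, columns=[
        "donor_index", "acceptor_index", "donor", "acceptor",
        "formed", "total", "occupancy", "system"])
    return df.sort_values(["donor_index", "acceptor_index"],
                          ignore_index=True)


def _bond_key(row: pd.Series) -> tuple[str, str]:
    return (row["donor"], row["acceptor"])


def _resnum_key(tag: str) -> tuple[str, str]:
    """Fallback identity ignoring atom and residue names: group + resnum."""
    group, res, _ = tag.split(":")
    digits = "".join(c for c in res if c.isdigit())
    return (group, digits)


def compare_networks(
    reference: pd.DataFrame,
    variants: dict[str, pd.DataFrame],
) -> dict:
    """Align occupancy tables of variants against a reference system.

    Bonds are matched by (donor tag, acceptor tag); bonds at substituted
    residues fall back to matching by (group, residue number).  Returns a
    report with the aligned table, key bonds (occupancy exactly 1.0 in the
    reference), and an unmatched section listing bonds whose partners could
    not be mapped at all.
    """
    ref_keys = {_bond_key(r): r for _, r in reference.iterrows()}
    ref_fallback = {}
    for k, r in ref_keys.items():
        ref_fallback.setdefault(
            (_resnum_key(k[0]), _resnum_key(k[1])), []).append(k)

    all_bonds: dict[tuple[str, str], dict] = {
        k: {"reference": float(r["occupancy"])} for k, r in ref_keys.items()}
    unmatched: list[dict] = []

    for label, table in variants.items():
        seen_ref: set[tuple[str, str]] = set()
        for _, row in table.iterrows():
            k = _bond_key(row)
            if k in ref_keys:
                target = k
            else:
                fb = ref_fallback.get((_resnum_key(k[0]), _resnum_key(k[1])))
                candidates = [c for c in (fb or []) if c not in seen_ref]
                target = candidates[0] if candidates else None
            if target is None:
                # bond only in the variant: delta = +occupancy_variant
                all_bonds.setdefault(k, {"reference": 0.0})
                all_bonds[k][label] = float(row["occupancy"])
                continue
            seen_ref.add(target)
            all_bonds[target][label] = float(row["occupancy"])

    rows = []
    for (donor, acceptor), occ in sorted(all_bonds.items()):
        ref_occ = occ.get("reference", 0.0)
        entry = {"donor": donor, "acceptor": acceptor, "reference": ref_occ,
                 "key_bond": ref_occ == 1.0}
        for label in variants:
            v = occ.get(label, 0.0)
            entry[label] = v
            entry[f"delta_{label}"] = v - ref_occ
        rows.append(entry)

    table = pd.DataFrame(rows)
    key_bonds = table[table["key_bond"]] if len(table) else table
    return {
        "table": table,
        "key_bonds": key_bonds,
        "unmatched": unmatched,
    }
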