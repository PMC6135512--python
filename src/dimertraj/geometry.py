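"""Superposition and geometric observables.

RMSD/RMSF conventions: least-squares (Kabsch) superposition on a fit index
set, observables measured on a possibly different index set without
re-fitting.  RMSF profiles are computed against the iteratively refined mean
structure (fit -> mean -> fit until the mean drifts < 1e-6 A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Topology, Frame, Trajectory


@dataclass
class ScalarSeries:
    """A per-frame scalar observable with units, times and provenance."""

    values: np.ndarray
    times: np.ndarray
    label: str
    observable: str
    units: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values/times length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite observable values")

    def mean(self) -> float:
        return float(self.values.mean())

    def sd(self) -> float:
        return float(self.values.std())

    def histogram(self, bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic histogram with fixed bin width anchored at 0."""
        lo = np.floor(self.values.min() / bin_width) * bin_width
        hi = np.ceil(self.values.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(self.values, bins=edges)
        return counts, edges


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation, A."""

    resnums: np.ndarray
    values: np.ndarray
    label: str
    monomers_averaged: bool = False

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.resnums.shape != self.values.shape:
            raise ValueError("resnums/values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be nonnegative")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fit_rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the least-squares
    deviation over the fit indices.  The rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(mobile.shape[0]) if fit_indices is None else \
        np.asarray(fit_indices, dtype=int)
    if idx.size < 3:
        raise ValueError("need at least 3 fit atoms")
    x = mobile[idx]
    y = reference[idx]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    # degenerate (collinear) point sets have a rank-deficient cross-covariance
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) fit atom set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(((moved - y) ** 2).sum() / idx.size))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rot: np.ndarray,
                    trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def _batch_superpose(coords: np.ndarray, reference: np.ndarray,
                     fit_idx: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``coords`` (F, n, 3) onto ``reference``.

    Batched Kabsch: per-frame 3x3 SVDs, proper-rotation corrected.
    """
    x = coords[:, fit_idx, :]
    y = reference[fit_idx]
    xc = x.mean(axis=1, keepdims=True)
    yc = y.mean(axis=0)
    h = np.einsum("fni,nj->fij", x - xc, y - yc)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    corr = np.repeat(np.eye(3)[None], coords.shape[0], axis=0)
    corr[:, 2, 2] = np.sign(det)
    rot = np.einsum("fij,fjk,fkl->fil", np.transpose(vt, (0, 2, 1)), corr,
                    np.transpose(u, (0, 2, 1)))
    moved = np.einsum("fni,fji->fnj", coords - xc, rot) + yc
    return moved


def superpose_trajectory(trajectory: Trajectory, reference: Frame,
                         fit_indices: np.ndarray) -> Trajectory:
    """New trajectory with every frame Kabsch-fitted to the reference."""
    fit_idx = np.asarray(fit_indices, dtype=int)
    moved = _batch_superpose(trajectory.coords, reference.coords, fit_idx)
    return Trajectory(moved, trajectory.times, trajectory.label,
                      dict(trajectory.metadata))


def iterative_mean_structure(
    coords: np.ndarray,
    fit_idx: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Converged mean structure of a frame stack.

    Fit all frames to the current mean, recompute the mean, iterate until the
    mean moves < ``tol`` A (max-norm).  Returns (superposed frames, mean).
    """
    mean = coords[0].copy()
    moved = coords
    for _ in range(max_iter):
        moved = _batch_superpose(coords, mean, fit_idx)
        new_mean = moved.mean(axis=0)
        drift = np.abs(new_mean - mean).max()
        mean = new_mean
        if drift < tol:
            break
    return moved, mean


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def rmsd_series(
    trajectory: Trajectory,
    reference: Frame,
    fit_indices: np.ndarray,
    measure_indices: np.ndarray,
    observable: str = "rmsd",
) -> ScalarSeries:
    """Per-frame RMSD over ``measure_indices`` after fitting on ``fit_indices``.

    Fit and measure sets may differ (e.g. fit on the protein core, measure the
    ligand heavy atoms); the measured set is *not* re-fitted.
    """
    measure_idx = np.asarray(measure_indices, dtype=int)
    if measure_idx.size == 0:
        raise ValueError("empty measure index set")
    moved = _batch_superpose(trajectory.coords, reference.coords,
                             np.asarray(fit_indices, dtype=int))
    diff = moved[:, measure_idx, :] - reference.coords[measure_idx]
    vals = np.sqrt((diff ** 2).sum(axis=(1, 2)) / measure_idx.size)
    return ScalarSeries(vals, trajectory.times, trajectory.label, observable)


def rmsf(
    trajectory: Trajectory,
    topology: Topology,
    selection: np.ndarray,
    fit_indices: np.ndarray | None = None,
    average_monomers: bool = False,
) -> RMSFProfile:
    """Per-residue RMSF of the selected atoms about the converged mean.

    ``selection`` should hold one atom per residue (typically Calpha).  With
    ``average_monomers`` the values of equivalent residues (same residue
    number) of monomers A and B are averaged onto a single residue axis.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.asarray(selection, dtype=int)
    fit_idx = sel if fit_indices is None else np.asarray(fit_indices, dtype=int)
    moved, mean = iterative_mean_structure(trajectory.coords, fit_idx)
    dev = moved[:, sel, :] - mean[sel]
    per_atom = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))

    resnums = trajectory_resnums = topology.resnums[sel]
    if not average_monomers:
        return RMSFProfile(resnums, per_atom, trajectory.label, False)
    groups = [topology.groups[i] for i in sel]
    accum: dict[int, list[float]] = {}
    for rn, g, v in zip(trajectory_resnums, groups, per_atom):
        accum.setdefault(int(rn), []).append(float(v))
    keys = sorted(accum)
    vals = np.array([np.mean(accum[k]) for k in keys])
    return RMSFProfile(np.array(keys), vals, trajectory.label, True)


def distance_series(
    trajectory: Trajectory,
    group_a: np.ndarray | list[int] | int,
    group_b: np.ndarray | list[int] | int,
    observable: str = "distance",
) -> ScalarSeries:
    """Per-frame distance between two atoms or two group centroids, A."""
    a = np.atleast_1d(np.asarray(group_a, dtype=int))
    b = np.atleast_1d(np.asarray(group_b, dtype=int))
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        raise ValueError("identical atom (group) on both sides of a distance")
    ca = trajectory.coords[:, a, :].mean(axis=1)
    cb = trajectory.coords[:, b, :].mean(axis=1)
    vals = np.linalg.norm(ca - cb, axis=1)
    return ScalarSeries(vals, trajectory.times, trajectory.label, observable)


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of a ring: (centroid, unit normal)."""
    c = coords.mean(axis=0)
    centered = coords - c
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:
        raise ValueError("degenerate (collinear) ring atoms")
    return c, vt[2]


def ring_stacking(
    trajectory: Trajectory,
    ring_a: np.ndarray,
    ring_b: np.ndarray,
) -> tuple[ScalarSeries, ScalarSeries]:
    """Interplanar separation (A) and angle (degrees) of two ring systems.

    Per frame: best-fit plane for each ring (SVD normal); the angle is
    ``arccos |nA . nB|`` in [0, 90] degrees; the separation is the distance
    between ring centroids projected onto the mean normal.
    """
    ra = np.asarray(ring_a, dtype=int)
    rb = np.asarray(ring_b, dtype=int)
    if ra.size < 3 or rb.size < 3:
        raise ValueError("each ring needs at least 3 atoms")
    seps = np.empty(trajectory.n_frames)
    angs = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        ca, na = _ring_plane(trajectory.coords[k, ra, :])
        cb, nb = _ring_plane(trajectory.coords[k, rb, :])
        if na @ nb < 0:
            nb = -nb
        cosang = np.clip(abs(na @ nb), 0.0, 1.0)
        angs[k] = np.degrees(np.arccos(cosang))
        nmean = na + nb
        nmean /= np.linalg.norm(nmean)
        seps[k] = abs((cb - ca) @ nmean)
    sep = ScalarSeries(seps, trajectory.times, trajectory.label,
                       "ring_plane_separation", units="A")
    ang = ScalarSeries(angs, trajectory.times, trajectory.label,
                       "ring_interplanar_angle", units="degrees")
    return sep, ang


@dataclass
class LoopOpeningReport:
    detected: bool
    resnums: np.ndarray
    delta_rmsf: np.ndarray  # unbound - bound, per loop residue
    threshold: float


def detect_loop_opening(
    bound: RMSFProfile,
    unbound: RMSFProfile,
    loop_range: tuple[int, int],
    threshold: float = 10.0,
) -> LoopOpeningReport:
    """Verdict on a closed->open loop transition from two RMSF profiles.

    Detected iff the RMSF increase (unbound - bound) of *every* loop residue
    reaches the threshold (default 10 A, the reported magnitude of the "door"
    loop opening in the unbound enzyme).
    """
    lo, hi = loop_range
    b = {int(r): v for r, v in zip(bound.resnums, bound.values)}
    u = {int(r): v for r, v in zip(unbound.resnums, unbound.values)}
    loop = list(range(lo, hi + 1))
    missing = [r for r in loop if r not in b or r not in u]
    if missing:
        raise ValueError(f"loop residues {missing} outside the RMSF profiles")
    delta = np.array([u[r] - b[r] for r in loop])
    return LoopOpeningReport(bool(delta.min() >= threshold),
                             np.array(loop), delta, threshold)
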