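"""Pooled principal component analysis of labeled trajectories and the
PC1 dimer-misalignment displacement statistic.

The model is fitted on frames pooled across systems (reference + variants):
frames are superposed onto the iteratively refined pooled mean over the
selected coordinate centers, the 3N x 3N Cartesian covariance (1/(n-1)
normalization, no mass weighting) is eigendecomposed, and eigenvectors are
sorted by descending eigenvalue.  Eigenvector signs follow a fixed
convention: the largest-|loading| coordinate of each component is positive.

A frame's displacement along a component is the inner product of its
superposed, mean-subtracted 3N coordinate vector with that component; the
reference system's mean displacement defines the zero of the scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import ScalarSeries, iterative_mean_structure, _batch_superpose
from .topology import Trajectory


@dataclass
class PCModel:
    selection: np.ndarray        # atom indices of the coordinate centers
    mean: np.ndarray             # (N, 3) pooled mean, A
    eigenvectors: np.ndarray     # (3N, 3N), columns sorted by eigenvalue desc
    eigenvalues: np.ndarray      # (3N,), A^2, descending
    provenance: dict = field(default_factory=dict)

    @property
    def n_centers(self) -> int:
        return self.mean.shape[0]

    def check_invariants(self, rtol: float = 1e-6) -> None:
        v = self.eigenvectors
        gram = v.T @ v
        if not np.allclose(gram, np.eye(v.shape[1]), atol=1e-8):
            raise ValueError("eigenvectors not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues not in descending order")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("negative eigenvalues")

    def save(self, prefix: str | Path) -> None:
        """Serialize to ``<prefix>.json`` (metadata) + ``<prefix>.npz``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez(prefix.with_suffix(".npz"),
                 selection=self.selection, mean=self.mean,
                 eigenvectors=self.eigenvectors,
                 eigenvalues=self.eigenvalues)
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, prefix: str | Path) -> "PCModel":
        prefix = Path(prefix)
        data = np.load(prefix.with_suffix(".npz"))
        with open(prefix.with_suffix(".json")) as fh:
            prov = json.load(fh)
        return cls(data["selection"], data["mean"], data["eigenvectors"],
                   data["eigenvalues"], prov)


@dataclass
class DisplacementSeries:
    """Per-frame scalar displacement (A) along one principal component."""

    values: np.ndarray
    times: np.ndarray
    label: str
    component: int
    reference_offset: float = 0.0

    def mean(self) -> float:
        return float(self.values.mean())

    def sd(self) -> float:
        return float(self.values.std())

    def to_scalar_series(self) -> ScalarSeries:
        return ScalarSeries(self.values, self.times, self.label,
                            f"pc{self.component + 1}_displacement")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-|loading| entry is positive."""
    out = vectors.copy()
    for c in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, c])))
        if out[k, c] < 0:
            out[:, c] = -out[:, c]
    return out


def fit_pc_model(
    trajectories: dict[str, Trajectory],
    selection: np.ndarray,
    last_ns: float | None = 800.0,
    stride_ns: float | None = 1.0,
) -> PCModel:
    """Fit the pooled PC model over the frame schedule of every system.

    ``selection`` must address the same atom identities in every trajectory
    (all systems share one topology layout in this package).
    """
    sel = np.asarray(selection, dtype=int)
    stacks = []
    counts: dict[str, int] = {}
    n_atoms = None
    for label in sorted(trajectories):
        traj = trajectories[label]
        if n_atoms is None:
            n_atoms = traj.n_atoms
        elif traj.n_atoms != n_atoms:
            raise ValueError(
                f"selection mismatch: system {label} has {traj.n_atoms} atoms, "
                f"expected {n_atoms}")
        win = traj.window(last_ns, stride_ns)
        stacks.append(win.coords[:, sel, :])
        counts[label] = win.n_frames
    pooled = np.concatenate(stacks, axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled frames")

    fit_idx = np.arange(sel.size)
    moved, mean = iterative_mean_structure(pooled, fit_idx)
    dev = (moved - mean).reshape(pooled.shape[0], -1)
    cov = dev.T @ dev / (pooled.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])

    model = PCModel(
        selection=sel,
        mean=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        provenance={
            "systems": counts,
            "n_frames_pooled": int(pooled.shape[0]),
            "n_centers": int(sel.size),
            "window_last_ns": last_ns,
            "stride_ns": stride_ns,
            "superposition": "iterative pooled-mean fit over the selection",
            "normalization": "1/(n-1), no mass weighting",
            "sign_convention": "largest-|loading| coordinate positive",
        },
    )
    model.check_invariants()
    return model


def project(model: PCModel, trajectory: Trajectory,
            component: int = 0) -> DisplacementSeries:
    """Displacement of every frame along one component.

    Per frame: superpose onto the model mean over the selection, subtract the
    mean, take the inner product with the component vector.
    """
    if not (0 <= component < model.eigenvectors.shape[1]):
        raise IndexError(
            f"component {component} out of range (3N = "
            f"{model.eigenvectors.shape[1]})")
    sel = model.selection
    if trajectory.n_atoms == sel.size:
        # trajectory already restricted to the coordinate centers
        sub = trajectory.coords
    else:
        sub = trajectory.coords[:, sel, :]
    moved = _batch_superpose(sub, model.mean, np.arange(sel.size))
    dev = (moved - model.mean).reshape(trajectory.n_frames, -1)
    vals = dev @ model.eigenvectors[:, component]
    return DisplacementSeries(vals, trajectory.times, trajectory.label,
                              component)


def zero_reference(
    series: dict[str, DisplacementSeries],
    reference_label: str,
) -> dict[str, DisplacementSeries]:
    """Subtract the reference system's mean displacement from every series."""
    if reference_label not in series:
        raise KeyError(f"reference system {reference_label!r} missing")
    offset = series[reference_label].mean()
    return {
        label: DisplacementSeries(s.values - offset, s.times, s.label,
                                  s.component, reference_offset=offset)
        for label, s in series.items()
    }


def ellipse_summary(
    x: np.ndarray | DisplacementSeries | ScalarSeries,
    y: np.ndarray | DisplacementSeries | ScalarSeries,
) -> tuple[float, float, float, float]:
    """Axis-aligned ellipse of paired series: (mean x, mean y, SD x, SD y)."""
    xv = x.values if hasattr(x, "values") else np.asarray(x, dtype=float)
    yv = y.values if hasattr(y, "values") else np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("paired series must have equal length")
    return (float(xv.mean()), float(yv.mean()),
            float(xv.std()), float(yv.std()))
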