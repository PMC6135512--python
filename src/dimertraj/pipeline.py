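"""Config-driven orchestration: load systems, run every analysis stage,
write per-stage CSV/JSON plus a hash-stable manifest.

Stage order: load -> geometry (RMSF, cofactor RMSD, stacking, triad
distances, loop verdict) -> hbond (occupancy, network comparison) ->
essential dynamics (pooled model, per-system displacement, reference
zeroing, displacement-vs-energy ellipses) -> energetics (EM/EE/EL/ET table,
per-residue pairwise decomposition vs reference) -> summary.

Every run is deterministic given the config and input files; the manifest
records SHA-256 hashes of all inputs and outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .topology import (
    Frame, SelectionSpec, SelectionTerm, Topology, Trajectory, select,
)
from . import io as dio
from .geometry import (
    rmsf, rmsd_series, distance_series, ring_stacking, detect_loop_opening,
)
from .hbond import HBondCriteria, occupancy_table, compare_networks
from .essential_dynamics import (
    fit_pc_model, project, zero_reference, ellipse_summary,
)
from .energetics import decompose_em_ee_el, pairwise_residue_decomposition
from .synthetic import SyntheticSpec, build_toy_dimer, generate_trajectory

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class SystemEntry(BaseModel):
    label: str
    topology: str
    sidecar: str
    trajectory: str
    t0_ns: float = 0.0
    dt_ns: float = 1.0


class ScheduleCfg(BaseModel):
    last_ns: float | None = 800.0
    stride_ns: float | None = 1.0


class PCACfg(BaseModel):
    residue_start: int = 40
    residue_stop: int = 403
    ligand_atom: str = "C6"


class LoopCfg(BaseModel):
    start: int = 15
    stop: int = 32
    threshold_A: float = 10.0
    unbound_label: str | None = None


class HBondCfg(BaseModel):
    distance_cutoff: float = 3.5
    angle_min_deg: float = 135.0


class StackingCfg(BaseModel):
    ring_a: list[str]
    ring_b: list[str]


class RunConfig(BaseModel):
    """Validated run configuration (YAML/JSON document)."""

    systems: list[SystemEntry]
    reference: str
    schedule: ScheduleCfg = Field(default_factory=ScheduleCfg)
    pca: PCACfg = Field(default_factory=PCACfg)
    loop: LoopCfg | None = None
    stacking: StackingCfg | None = None
    triad: list[list[str]] | None = None
    hbond: HBondCfg = Field(default_factory=HBondCfg)
    rmsd_fit: list[int] | None = None      # [start, stop] core Calpha fit range
    outdir: str = "out"
    seed: int = 1
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        labels = [s.label for s in self.systems]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate system labels")
        if labels.count(self.reference) != 1:
            raise ValueError(
                f"reference label {self.reference!r} must name exactly one "
                f"declared system (got {labels})")
        paths = [p for s in self.systems
                 for p in (s.topology, s.sidecar, s.trajectory)]
        if len(set(paths)) != len(paths):
            raise ValueError("system input paths must be distinct")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _atom_key(top: Topology, key: str) -> int:
    group, resnum, name = key.split(":")
    return top.index_of(group, int(resnum), name)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig, config_dir: str | Path = ".") -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with the stage name; partial outputs are flagged
    incomplete in the manifest.
    """
    config_dir = Path(config_dir)
    outdir = Path(config.outdir)
    if not outdir.is_absolute():
        outdir = config_dir / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dimertraj")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())

    manifest: dict = {
        "config": config.model_dump(),
        "versions": {"dimertraj": __version__},
        "inputs": {},
        "outputs": {},
        "stages": {},
        "complete": False,
    }
    stage = "load"
    t_start = time.time()
    try:
        # ------------------------------------------------------------ load
        log.info("stage load: %d systems", len(config.systems))
        tops: dict[str, Topology] = {}
        refs: dict[str, np.ndarray] = {}
        trajs: dict[str, Trajectory] = {}
        for entry in config.systems:
            top_path = config_dir / entry.topology
            sidecar_path = config_dir / entry.sidecar
            traj_path = config_dir / entry.trajectory
            for p in (top_path, sidecar_path, traj_path):
                manifest["inputs"][str(p)] = _sha256(p)
            top, ref = dio.read_pdb(top_path)
            dio.read_parameter_sidecar(sidecar_path, top)
            traj = dio.read_trajectory(traj_path, top, label=entry.label,
                                       times=(entry.t0_ns, entry.dt_ns))
            tops[entry.label] = top
            refs[entry.label] = ref.coords
            trajs[entry.label] = traj
            log.info("loaded %s: %d atoms, %d frames", entry.label,
                     top.n_atoms, traj.n_frames)

        sched = config.schedule
        unbound = config.loop.unbound_label if config.loop else None
        main_labels = [s.label for s in config.systems if s.label != unbound]
        ref_label = config.reference

        # -------------------------------------------------------- geometry
        stage = "geometry"
        log.info("stage geometry")
        rmsf_profiles = {}
        rmsd_rows = []
        for label in [s.label for s in config.systems]:
            top = tops[label]
            traj = trajs[label].window(sched.last_ns, sched.stride_ns)
            ca = select(top, SelectionSpec((SelectionTerm(
                groups=("A", "B"), name="CA"),)))
            # superpose on the stable scaffold: a mobile loop inside the fit
            # set would absorb part of its own fluctuation into the fit
            if config.loop is not None:
                scaffold = np.array([
                    i for i in ca
                    if not (config.loop.start <= top.resnums[i]
                            <= config.loop.stop)], dtype=int)
            else:
                scaffold = ca
            prof = rmsf(traj, top, ca, fit_indices=scaffold,
                        average_monomers=True)
            rmsf_profiles[label] = prof
            _write_csv(pd.DataFrame({
                "system": label, "resnum": prof.resnums,
                "observable": "rmsf", "value": prof.values, "units": "A",
            }), outdir / "geometry" / f"rmsf_{label}.csv")

            if config.rmsd_fit:
                lo, hi = config.rmsd_fit
                fit_idx = select(top, SelectionSpec((SelectionTerm(
                    groups=("A", "B"), resnum_range=(lo, hi), name="CA"),)))
                fit_idx = np.intersect1d(fit_idx, scaffold)
            else:
                fit_idx = scaffold
            ref_frame = Frame(refs[label])
            site_series = []
            for site in ("L1", "L2"):
                lig = top.group_indices(site)
                if lig.size == 0:
                    continue
                s = rmsd_series(traj, ref_frame, fit_idx, lig,
                                observable=f"ligand_rmsd_{site}")
                site_series.append(s)
                _write_csv(pd.DataFrame({
                    "system": label, "time_ns": s.times,
                    "observable": s.observable, "value": s.values,
                    "units": "A",
                }), outdir / "geometry" / f"rmsd_ligand_{site}_{label}.csv")
            if site_series:
                pooled = np.concatenate([s.values for s in site_series])
                rmsd_rows.append({
                    "system": label, "mean_A": pooled.mean(),
                    "sd_A": pooled.std(), "n_frames": pooled.size,
                })

            if config.stacking is not None:
                ra = np.array([_atom_key(top, k) for k in config.stacking.ring_a])
                rb = np.array([_atom_key(top, k) for k in config.stacking.ring_b])
                sep, ang = ring_stacking(traj, ra, rb)
                _write_csv(pd.DataFrame({
                    "system": label, "time_ns": sep.times,
                    "separation_A": sep.values, "angle_deg": ang.values,
                }), outdir / "geometry" / f"stacking_{label}.csv")

            if config.triad:
                cols = {"system": label, "time_ns": traj.times}
                for pair in config.triad:
                    i = _atom_key(top, pair[0])
                    j = _atom_key(top, pair[1])
                    s = distance_series(traj, i, j)
                    cols[f"{pair[0]}--{pair[1]}"] = s.values
                _write_csv(pd.DataFrame(cols),
                           outdir / "geometry" / f"triad_{label}.csv")

        if rmsd_rows:
            _write_csv(pd.DataFrame(rmsd_rows),
                       outdir / "geometry" / "rmsd_summary.csv")

        if config.loop and unbound and unbound in rmsf_profiles:
            report = detect_loop_opening(
                rmsf_profiles[ref_label], rmsf_profiles[unbound],
                (config.loop.start, config.loop.stop),
                config.loop.threshold_A)
            _write_json({
                "detected": report.detected,
                "threshold_A": report.threshold,
                "bound_system": ref_label,
                "unbound_system": unbound,
                "delta_rmsf_A": dict(zip(map(int, report.resnums),
                                         map(float, report.delta_rmsf))),
            }, outdir / "geometry" / "loop_report.json")

        # ----------------------------------------------------------- hbond
        stage = "hbond"
        log.info("stage hbond")
        criteria = HBondCriteria(config.hbond.distance_cutoff,
                                 config.hbond.angle_min_deg)
        occ_tables = {}
        for label in main_labels:
            traj = trajs[label].window(sched.last_ns, sched.stride_ns)
            table = occupancy_table(traj, tops[label], criteria,
                                    restriction="ligand-protein")
            occ_tables[label] = table
            _write_csv(table, outdir / "hbond" / f"occupancy_{label}.csv")
        comparison = compare_networks(
            occ_tables[ref_label],
            {k: v for k, v in occ_tables.items() if k != ref_label})
        _write_csv(comparison["table"], outdir / "hbond" / "network_comparison.csv")
        _write_json({
            "reference": ref_label,
            "key_bonds": comparison["key_bonds"][
                ["donor", "acceptor", "reference"]].to_dict("records"),
            "n_bonds": int(len(comparison["table"])),
            "unmatched": comparison["unmatched"],
        }, outdir / "hbond" / "network_report.json")

        # ---------------------------------------------- essential dynamics
        stage = "essential_dynamics"
        log.info("stage essential dynamics")
        ref_top = tops[ref_label]
        pca_sel = select(ref_top, SelectionSpec.ca_plus_ligand_atom(
            config.pca.residue_start, config.pca.residue_stop,
            config.pca.ligand_atom))
        model = fit_pc_model({k: trajs[k] for k in main_labels}, pca_sel,
                             sched.last_ns, sched.stride_ns)
        model.save(outdir / "pca" / "model")
        series = {k: project(model, trajs[k].window(sched.last_ns,
                                                    sched.stride_ns))
                  for k in main_labels}
        zeroed = zero_reference(series, ref_label)
        disp_rows = []
        for label, s in zeroed.items():
            for t, v in zip(s.times, s.values):
                disp_rows.append({"system": label, "time_ns": t,
                                  "pc_index": 1, "displacement_A": v})
        _write_csv(pd.DataFrame(disp_rows), outdir / "pca" / "displacements.csv")

        # ------------------------------------------------------ energetics
        stage = "energetics"
        log.info("stage energetics")
        breakdowns = {}
        summary_rows = []
        for label in main_labels:
            bd = decompose_em_ee_el(tops[label], trajs[label],
                                    sched.last_ns, sched.stride_ns)
            bd.check_identity()
            breakdowns[label] = bd
            _write_csv(bd.per_frame,
                       outdir / "energy" / f"breakdown_{label}.csv")
            s = bd.summary().set_index("term")
            summary_rows.append({
                "system": label,
                "EM_kcal": s.loc["EM", "mean"], "EM_sd": s.loc["EM", "sd"],
                "EM_block_se": s.loc["EM", "block_se"],
                "EE_kcal": s.loc["EE", "mean"], "EE_sd": s.loc["EE", "sd"],
                "EE_block_se": s.loc["EE", "block_se"],
                "EL_kcal": s.loc["EL", "mean"], "EL_sd": s.loc["EL", "sd"],
                "EL_block_se": s.loc["EL", "block_se"],
                "ET_kcal": s.loc["ET", "mean"], "ET_sd": s.loc["ET", "sd"],
                "ET_block_se": s.loc["ET", "block_se"],
            })
        _write_csv(pd.DataFrame(summary_rows),
                   outdir / "energy" / "energy_table.csv")

        # displacement-vs-energy ellipses (means relative to reference)
        ellipse_rows = []
        for term in ("EM", "EE", "EL"):
            ref_mean = breakdowns[ref_label].per_frame[term].mean()
            for label in main_labels:
                e = breakdowns[label].per_frame[term].to_numpy() - ref_mean
                d = zeroed[label].values
                n = min(len(e), len(d))
                cx, cy, sx, sy = ellipse_summary(d[:n], e[:n])
                ellipse_rows.append({
                    "system": label, "energy_term": term,
                    "mean_displacement_A": cx, "mean_energy_kcal": cy,
                    "sd_displacement_A": sx, "sd_energy_kcal": sy,
                })
        _write_csv(pd.DataFrame(ellipse_rows),
                   outdir / "energy" / "ellipses.csv")

        # pairwise decompositions relative to the reference
        ref_matrices = {}
        for partition, site in (("interface", "L1"), ("ligand", "L1"),
                                ("ligand", "L2")):
            key = partition if partition == "interface" else f"{partition}_{site}"
            ref_matrices[key] = pairwise_residue_decomposition(
                tops[ref_label], trajs[ref_label], partition, site,
                sched.last_ns, sched.stride_ns)
            _write_csv(ref_matrices[key].to_frame(),
                       outdir / "energy" / f"pairwise_{key}_{ref_label}.csv")
        for label in main_labels:
            if label == ref_label:
                continue
            for partition, site in (("interface", "L1"), ("ligand", "L1"),
                                    ("ligand", "L2")):
                key = partition if partition == "interface" \
                    else f"{partition}_{site}"
                mat = pairwise_residue_decomposition(
                    tops[label], trajs[label], partition, site,
                    sched.last_ns, sched.stride_ns,
                    reference=ref_matrices[key])
                _write_csv(mat.to_frame(),
                           outdir / "energy" / f"pairwise_{key}_{label}_rel.csv")

        # --------------------------------------------------------- summary
        stage = "summary"
        log.info("stage summary")
        energy_table = pd.read_csv(outdir / "energy" / "energy_table.csv")
        disp = pd.read_csv(outdir / "pca" / "displacements.csv")
        summary = {
            "systems": main_labels,
            "reference": ref_label,
            "pooled_pca_frames": int(model.provenance["n_frames_pooled"]),
            "pca_centers": int(model.provenance["n_centers"]),
            "mean_displacement_A": {
                label: float(g["displacement_A"].mean())
                for label, g in disp.groupby("system")},
            "energy_table": energy_table.to_dict("records"),
        }
        if (outdir / "geometry" / "rmsd_summary.csv").exists():
            summary["ligand_rmsd"] = pd.read_csv(
                outdir / "geometry" / "rmsd_summary.csv").to_dict("records")
        if (outdir / "geometry" / "loop_report.json").exists():
            with open(outdir / "geometry" / "loop_report.json") as fh:
                loop_rep = json.load(fh)
            summary["loop_opening_detected"] = loop_rep["detected"]
        _write_json(summary, outdir / "summary.json")

        manifest["stages"] = {
            "pooled_pca_frames": int(model.provenance["n_frames_pooled"]),
            "n_systems": len(main_labels),
            "schedule": {"last_ns": sched.last_ns,
                         "stride_ns": sched.stride_ns},
        }
        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _finalize_manifest(manifest, outdir)
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, str(exc)) from exc

    log.info("pipeline complete in %.1f s", time.time() - t_start)
    _finalize_manifest(manifest, outdir)
    root.removeHandler(handler)
    handler.close()
    return outdir


def _finalize_manifest(manifest: dict, outdir: Path) -> None:
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "run.log"):
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    _write_json(manifest, outdir / "manifest.json")


# ---------------------------------------------------------------------------
# Demo workspace
# ---------------------------------------------------------------------------

def make_demo(
    outdir: str | Path,
    seed: int = 1,
    residues_per_monomer: int = 48,
    n_frames: int = 250,
    last_ns: float = 200.0,
    force: bool = False,
) -> Path:
    """Write a ready-to-run synthetic four-system workspace.

    Produces toy dimer topology PDBs, parameter sidecars, XYZ trajectories
    for the reference (WT), the three variants, and a ligand-free-style
    "WT_apo" run with a planted loop opening, plus ``config.yaml``.
    Returns the config path.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(
        residues_per_monomer=residues_per_monomer,
        n_frames=n_frames,
        seed=seed,
    )
    top, ref = build_toy_dimer(spec)
    apo_spec = SyntheticSpec(
        residues_per_monomer=residues_per_monomer,
        n_frames=n_frames,
        seed=seed,
        loop_opening=12.0,
        amplitude_means={**spec.amplitude_means, "WT_apo": 0.0},
    )

    labels = ["WT", "E266K", "R267H", "P300L"]
    systems = []
    for label in labels + ["WT_apo"]:
        use_spec = apo_spec if label == "WT_apo" else spec
        traj = generate_trajectory(top, ref, use_spec, label)
        dio.write_pdb(top, Frame(ref.coords), outdir / f"{label}_topology.pdb")
        dio.write_parameter_sidecar(top, outdir / f"{label}_params.tsv")
        dio.write_xyz(top, traj, outdir / f"{label}_traj.xyz")
        systems.append({
            "label": label,
            "topology": f"{label}_topology.pdb",
            "sidecar": f"{label}_params.tsv",
            "trajectory": f"{label}_traj.xyz",
            "t0_ns": 0.0,
            "dt_ns": spec.dt_ns,
        })

    r = residues_per_monomer
    core_lo, core_hi = top.metadata["core_range"]
    ring_res = top.metadata["ring_residue"]
    triad = top.metadata["triad_residues"]
    config = {
        "systems": systems,
        "reference": "WT",
        "schedule": {"last_ns": last_ns, "stride_ns": spec.dt_ns},
        "pca": {"residue_start": 1, "residue_stop": r, "ligand_atom": "C6"},
        "loop": {"start": spec.loop_range[0], "stop": spec.loop_range[1],
                 "threshold_A": 10.0, "unbound_label": "WT_apo"},
        "stacking": {
            "ring_a": [f"A:{ring_res}:RC{k}" for k in range(1, 7)],
            "ring_b": [f"L1:500:{n}" for n in
                       ("N1", "C2", "C3", "C4", "C5", "C6")],
        },
        "triad": [[f"A:{triad[0]}:NE2", f"A:{triad[1]}:OG1"],
                  [f"A:{triad[1]}:OG1", f"A:{triad[2]}:ND1"]],
        "hbond": {"distance_cutoff": 3.5, "angle_min_deg": 135.0},
        "rmsd_fit": [core_lo, core_hi],
        "outdir": "out",
        "seed": seed,
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
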