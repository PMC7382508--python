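"""End-to-end orchestration from a single YAML config.

A run proceeds distances → events → PMF/ΔG → (RMSD) → density →
(pathways) → k_on and drops all artifacts into the configured output
directory: ``events.csv``, ``pmf.csv``, ``density.dx`` and a flat
``report.yaml`` that also records every constant of the free-energy
estimator (δ shift, bulk anchor, cutoff, C⁰, T) — those constants are the
reproducibility-critical surface of the whole analysis.

Input is either a ``simulate:`` block (synthetic Brownian-dynamics demo,
fully self-contained) or an ``inputs:`` block pointing at structure +
trajectory files with pocket/ligand selections (1-based bead ids, GRO/PDB
habit).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import synthetic
from .events import (EventCriteria, detect_events, estimate_kon,
                     events_to_dataframe, ligand_concentration, summarize)
from .free_energy import PMFParams, binding_free_energy, bootstrap_error
from .density import accumulate, fold_over_bulk, write_dx
from .trajectory import (Selection, distance_series, read_structure,
                         read_trajectory)

logger = logging.getLogger("cgbind")

__all__ = ["RunConfig", "load_config", "run"]


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring for the layout)."""

    output_dir: Path
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    criteria: EventCriteria = field(default_factory=EventCriteria)
    pmf: PMFParams = field(default_factory=PMFParams)
    n_ligands: int = 1
    bootstrap_resamples: int = 200
    density_spacing: float | None = 0.1
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "output_dir" not in raw:
        raise ValueError("config must set output_dir")
    cfg = RunConfig(
        output_dir=Path(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
        simulate=raw.get("simulate"),
        inputs=raw.get("inputs"),
        criteria=EventCriteria(**raw.get("criteria", {})),
        pmf=PMFParams(**raw.get("pmf", {})),
        n_ligands=int(raw.get("n_ligands", 1)),
        bootstrap_resamples=int(raw.get("bootstrap", {}).get("n_boot", 200)),
        density_spacing=raw.get("density", {}).get("spacing", 0.1)
        if raw.get("density", {}).get("enabled", True) else None,
        raw=raw,
    )
    if cfg.inputs is not None:
        for key in ("trajectories",):
            if key not in cfg.inputs:
                raise ValueError(f"inputs block must set {key!r}")
        for p in cfg.inputs["trajectories"]:
            if not Path(p).exists():
                raise ValueError(f"trajectory file not found: {p}")
    return cfg


def _stage(name: str, report: dict):
    """Context manager recording stage wall time and naming failures."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: FAILED (%s)", name, exc)
                report["failed_stage"] = name
            else:
                logger.info("stage %s: done in %.2f s", name, dt)
            return False

    return _Ctx()


def _load_series(cfg: RunConfig):
    """Returns (series list, frames list, pocket sel, ligand sel, box)."""
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        n_replicas = int(sim.pop("n_replicas", 4))
        model = synthetic.SyntheticModel(seed=cfg.seed, **sim.get("model", {}))
        results = synthetic.simulate_ensemble(model, n_replicas)
        frames = [r.frames for r in results]
        pocket = results[0].pocket
        ligand = results[0].ligand
    else:
        inp = cfg.inputs
        fmt = inp.get("format", "table")
        topology = None
        if "structure" in inp:
            topology = read_structure(inp["structure"]).topology
        frames = [
            read_trajectory(p, fmt=fmt, topology=topology)
            for p in inp["trajectories"]
        ]
        pocket = Selection("pocket", np.asarray(inp.get("pocket", [1])) - 1)
        ligand = Selection("ligand", np.asarray(inp.get("ligand", [2])) - 1)
    series = [
        distance_series(fs, pocket, ligand, replica_id=f"replica-{i}")
        for i, fs in enumerate(frames)
    ]
    return series, frames, pocket, ligand, frames[0].box


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the pipeline; returns (and writes) the report dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "constants": {
            "shift_nm": config.pmf.shift,
            "r_ref_nm": config.pmf.r_ref,
            "r_c_nm": config.pmf.r_c,
            "c0_nm^-3": config.pmf.c0,
            "temperature_K": config.pmf.temperature,
            "bin_width_nm": config.pmf.bin_width,
            "r_on_nm": config.criteria.r_on,
            "r_off_nm": config.criteria.r_off,
            "min_dwell_us": config.criteria.min_dwell,
        },
    }
    try:
        with _stage("distances", report):
            series, frames, pocket, ligand, box = _load_series(config)
            report["n_replicas"] = len(series)
            report["total_time_us"] = float(sum(s.duration for s in series))

        with _stage("events", report):
            events_by_replica = {
                s.replica_id: detect_events(s, config.criteria) for s in series
            }
            durations = {s.replica_id: s.duration for s in series}
            summary = summarize(events_by_replica, durations)
            report["events"] = summary.as_dict()
            all_events = [ev for evs in events_by_replica.values() for ev in evs]
            events_to_dataframe(all_events).to_csv(out / "events.csv", index=False)

        with _stage("pmf", report):
            undersampled = summary.replicas_without_unbinding > 0
            dg, pmf = binding_free_energy(series, config.pmf,
                                          undersampled_bulk=undersampled)
            if len(series) >= 2 and config.bootstrap_resamples > 0:
                dg.error = bootstrap_error(series, config.pmf,
                                           n_boot=config.bootstrap_resamples,
                                           seed=config.seed)
            report["free_energy"] = dg.as_dict()
            pmf.to_dataframe().to_csv(out / "pmf.csv", index=False)

        if config.raw.get("reference_pose"):
            with _stage("rmsd", report):
                from .pose import SymmetricLigand, rmsd_series, symmetry_rmsd

                ref_coords = np.loadtxt(config.raw["reference_pose"], ndmin=2)
                perms = [tuple(p) for p in config.raw.get("symmetry", [])]
                reference = SymmetricLigand(ref_coords, perms)
                if all_events and pocket.indices.size >= 3:
                    pose_rmsd = rmsd_series(frames[0], all_events, reference,
                                            pocket, ligand)
                    rmsd_vals = pose_rmsd.rmsd
                    times = pose_rmsd.times
                elif all_events:
                    # point pocket: frames already live in the fixed frame
                    rmsd_vals, times = [], []
                    for fs, evs in zip(frames, (events_by_replica[s.replica_id]
                                                for s in series)):
                        t_end = fs.times[-1]
                        bound = np.zeros(fs.n_frames, dtype=bool)
                        for ev in evs:
                            stop = ev.t_unbind if ev.t_unbind is not None else t_end
                            bound |= (fs.times >= ev.t_bind) & (fs.times <= stop)
                        for i in np.flatnonzero(bound):
                            rmsd_vals.append(symmetry_rmsd(
                                fs.positions[i][ligand.indices], reference))
                            times.append(fs.times[i])
                    rmsd_vals = np.asarray(rmsd_vals)
                    times = np.asarray(times)
                else:
                    rmsd_vals = np.array([])
                    times = np.array([])
                if rmsd_vals.size:
                    report["rmsd"] = {
                        "mean_A": float(np.mean(rmsd_vals)),
                        "sd_A": float(np.std(rmsd_vals, ddof=1))
                        if rmsd_vals.size > 1 else 0.0,
                        "n_bound_frames": int(rmsd_vals.size),
                    }
                else:
                    report["rmsd"] = "no bound frames"
        else:
            logger.warning("no reference pose configured; RMSD stage skipped")
            report["rmsd"] = "skipped (no reference pose)"

        if config.density_spacing:
            with _stage("density", report):
                grid = accumulate(frames, ligand, alignment=None,
                                  spacing=config.density_spacing)
                ratio = fold_over_bulk(grid)
                write_dx(ratio, grid.origin, grid.spacing, out / "density.dx",
                         name="fold_over_bulk")
                report["density"] = {
                    "n_samples": grid.n_samples,
                    "bulk_density_per_voxel": grid.bulk_density,
                    "max_fold_over_bulk": float(np.max(ratio)),
                }

        with _stage("kinetics", report):
            conc = ligand_concentration(config.n_ligands, box)
            report["concentration_mM"] = conc
            if summary.total_bind > 0 and summary.bound_fraction < 1.0:
                report["kon_per_s_per_uM"] = estimate_kon(
                    summary.total_bind, summary.total_time,
                    summary.bound_fraction, conc,
                )
    finally:
        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(_yaml_ready(report), fh, sort_keys=True)
    return report


def _yaml_ready(obj):
    if isinstance(obj, dict):
        return {k: _yaml_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_ready(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
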