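"""Configuration-driven orchestration of the full analysis.

Stage order follows the data dependencies: superpose -> events -> kinetics;
superpose -> fields; events + trajectories -> site geometry.  A failure in
one branch is recorded in the manifest and does not abort independent
branches.

Determinism: in synthetic mode the same (config, seed) produces
byte-identical CSV/JSON data outputs.  The manifest itself is therefore
kept deterministic (config hash, seed, version, stage status, applied
defaults); per-stage wall times go to a separate ``timings.json`` sidecar
so they cannot perturb reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .config import AnalysisConfig
from .events import (
    EventTable,
    GateDefinition,
    SiteDefinition,
    VESTIBULE,
    binding_order_counts,
    build_event_table,
    detect_release,
    first_binding_times,
)
from .fields import GridSpec, accumulate_density, accumulate_displacement, write_grid
from .geometry import (
    compactness_series,
    rmsd_matrix,
    running_average,
    split_pre_post,
    split_summaries_to_dataframe,
)
from .kinetics import (
    FitError,
    bootstrap_rate_ci,
    cumulative_curve,
    fit_constrained_monoexponential,
    mle_censored_exponential,
)
from .synthetic import generate_replica_set, write_replica_set
from .traj_core import (
    ReplicaSet,
    read_topology,
    read_trajectory,
    select_atoms,
    select_ions,
    superpose_trajectory,
)

__all__ = ["ReportBundle", "run_pipeline", "StageFailure"]

log = logging.getLogger("ionbind")


@dataclass
class StageFailure:
    stage: str
    error: str


@dataclass
class ReportBundle:
    """Everything a run produced, plus the manifest describing it."""

    output_dir: Path
    manifest: dict
    event_table: Optional[EventTable] = None
    kinetic_fits: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    geometry_summaries: dict = field(default_factory=dict)
    failures: list[StageFailure] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _config_hash(config: AnalysisConfig) -> str:
    # identify the analysis, not its destination: output location and log
    # verbosity do not change any result
    payload = config.model_dump(mode="json")
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def _load_real(config: AnalysisConfig) -> ReplicaSet:
    block = config.real
    topology = read_topology(block.topology)
    trajs = [
        read_trajectory(topology, p, format=block.trajectory_format, replica_id=i)
        for i, p in enumerate(block.trajectories)
    ]
    return ReplicaSet(
        topology=topology,
        trajectories=trajs,
        reference_frame=trajs[0].frame(0),
        ion_concentration=block.concentration_molar,
    )


def run_pipeline(
    config: AnalysisConfig,
    applied_defaults: Optional[list[str]] = None,
    out_dir: Optional[str | Path] = None,
) -> ReportBundle:
    """Execute every stage and write the report bundle to ``output_dir``."""
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "package": "ionbind",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "applied_defaults": sorted(applied_defaults or []),
        "stages": {},
        "outputs": [],
    }
    timings: dict[str, float] = {}
    bundle = ReportBundle(output_dir=out, manifest=manifest)

    def record(stage: str, status: str, error: str | None = None) -> None:
        manifest["stages"][stage] = {"status": status}
        if error:
            manifest["stages"][stage]["error"] = error
            bundle.failures.append(StageFailure(stage=stage, error=error))

    def emit(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    # ---------------------------------------------------------------- input
    t0 = time.perf_counter()
    ground_truth = None
    try:
        if config.synthetic is not None:
            syn = config.synthetic.to_synthetic_config(config.seed)
            replica_set, ground_truth = generate_replica_set(syn)
            emit(ground_truth.to_json(out / "ground_truth.json"))
            if config.synthetic.write_trajectories:
                write_replica_set(replica_set, ground_truth, out / "replicas")
        else:
            replica_set = _load_real(config)
        record("input", "ok")
    except Exception as exc:
        record("input", "failed", f"{type(exc).__name__}: {exc}")
        log.error("input stage failed:\n%s", traceback.format_exc())
        _finalise(bundle, out, timings, t0)
        return bundle
    timings["input"] = time.perf_counter() - t0

    topology = replica_set.topology
    try:
        ion_sel = select_ions(topology, config.ion_name)
    except Exception as exc:
        record("input", "failed", f"ion selection: {exc}")
        _finalise(bundle, out, timings, t0)
        return bundle

    # ------------------------------------------------------------ superpose
    t1 = time.perf_counter()
    try:
        fit_sel = select_atoms(topology, config.fit_selection)
        aligned = [
            superpose_trajectory(t, replica_set.reference_frame, fit_sel)
            for t in replica_set.trajectories
        ]
        replica_set = ReplicaSet(
            topology=topology,
            trajectories=aligned,
            reference_frame=replica_set.reference_frame,
            ion_concentration=replica_set.ion_concentration,
        )
        record("superpose", "ok")
    except Exception as exc:
        record("superpose", "failed", f"{type(exc).__name__}: {exc}")
        log.error("superpose failed:\n%s", traceback.format_exc())
        _finalise(bundle, out, timings, t1)
        return bundle
    timings["superpose"] = time.perf_counter() - t1

    # --------------------------------------------------------------- events
    t2 = time.perf_counter()
    site_defs: list[SiteDefinition] = []
    event_table = None
    try:
        gate = GateDefinition(
            anchor_a=select_atoms(topology, config.gate.anchor_a),
            anchor_b=select_atoms(topology, config.gate.anchor_b),
            vestibule_axis=config.gate.axis,
            lateral_radius=config.gate.lateral_radius_nm,
            min_dwell=config.gate.min_dwell_ns,
        )
        for s in config.sites:
            try:
                site_defs.append(
                    SiteDefinition(
                        name=s.name,
                        coordinating=select_atoms(topology, s.coordinating),
                        entry_cutoff=s.entry_cutoff_nm,
                        exit_cutoff=s.exit_cutoff_nm,
                        min_dwell=s.min_dwell_ns,
                    )
                )
            except Exception as exc:
                log.warning("site %s skipped: %s", s.name, exc)
                manifest["stages"][f"site:{s.name}"] = {
                    "status": "skipped", "reason": str(exc),
                }
        event_table = build_event_table(
            replica_set.trajectories, gate, site_defs, ion_sel,
            n_replicas=replica_set.n_replicas,
        )
        bundle.event_table = event_table
        emit(event_table.to_csv(out / "events.csv"))
        emit(event_table.to_json(out / "events.json"))
        order = binding_order_counts(event_table)
        _json_dump(order, emit(out / "binding_order.json"))
        record("events", "ok")
    except Exception as exc:
        record("events", "failed", f"{type(exc).__name__}: {exc}")
        log.error("events failed:\n%s", traceback.format_exc())
    timings["events"] = time.perf_counter() - t2

    # ------------------------------------------------------------- kinetics
    t3 = time.perf_counter()
    if event_table is not None:
        try:
            rows = []
            duration = event_table.duration
            conc = replica_set.ion_concentration
            site_names = [VESTIBULE] + [s.name for s in site_defs]
            for name in site_names:
                try:
                    firsts = first_binding_times(event_table, name)
                except KeyError:
                    log.info("kinetics: no %s events; site skipped", name)
                    continue
                try:
                    mle = mle_censored_exponential(firsts, duration)
                except FitError as exc:
                    log.info("kinetics: %s skipped (%s)", name, exc)
                    continue
                ci = (float("nan"), float("nan"))
                if config.kinetics.bootstrap:
                    ci = bootstrap_rate_ci(
                        firsts, duration, n_boot=config.kinetics.n_boot,
                        seed=config.seed,
                    )
                curve = cumulative_curve(firsts, duration, config.kinetics.grid_dt_ns)
                fit = fit_constrained_monoexponential(curve, concentration=conc, ci_95=ci)
                bundle.kinetic_fits[name] = fit
                rows.append(
                    {
                        "site": name,
                        "b_per_ns": fit.b,
                        "t_half_ns": fit.t_half,
                        "k_on_per_M_per_s": fit.k_on,
                        "b_mle_per_ns": mle,
                        "ci_low_per_ns": fit.ci_95[0],
                        "ci_high_per_ns": fit.ci_95[1],
                        "n_events": fit.n_events,
                        "n_censored": fit.n_censored,
                        "sse": fit.residual_sse,
                    }
                )
            import pandas as pd

            df = pd.DataFrame(rows)
            df.to_csv(out / "kinetics.csv", index=False, float_format="%.8g")
            emit(out / "kinetics.csv")
            _json_dump(
                {r["site"]: {k: v for k, v in r.items() if k != "site"} for r in rows},
                emit(out / "kinetics.json"),
            )
            record("kinetics", "ok")
        except Exception as exc:
            record("kinetics", "failed", f"{type(exc).__name__}: {exc}")
            log.error("kinetics failed:\n%s", traceback.format_exc())
    else:
        record("kinetics", "skipped", None)
        manifest["stages"]["kinetics"] = {"status": "skipped", "reason": "no events"}
    timings["kinetics"] = time.perf_counter() - t3

    # --------------------------------------------------------------- fields
    t4 = time.perf_counter()
    try:
        g = config.grid
        if g.origin_nm is not None and g.shape is not None:
            spec = GridSpec(origin=g.origin_nm, spacing=g.spacing_nm, shape=g.shape)
        else:
            box = replica_set.trajectories[0].box
            spec = GridSpec.covering_box(box, spacing=g.spacing_nm)
        dt = replica_set.trajectories[0].dt
        density = accumulate_density(
            replica_set, ion_sel, spec,
            sample_interval=max(g.density_sample_interval_ns, dt),
        )
        displacement = accumulate_displacement(
            replica_set, ion_sel, spec, lag=max(g.displacement_lag_ns, dt),
        )
        bundle.grids = {"density": density, "displacement": displacement}
        emit(write_grid(density, out / "density.dx"))
        emit(write_grid(displacement, out / "displacement.dx"))
        record("fields", "ok")
    except Exception as exc:
        record("fields", "failed", f"{type(exc).__name__}: {exc}")
        log.error("fields failed:\n%s", traceback.format_exc())
    timings["fields"] = time.perf_counter() - t4

    # ------------------------------------------------------------- geometry
    t5 = time.perf_counter()
    if event_table is not None and site_defs:
        try:
            import pandas as pd

            all_series = []
            summaries = []
            for site in site_defs:
                try:
                    firsts = first_binding_times(event_table, site.name)
                except KeyError:
                    firsts = [None] * replica_set.n_replicas
                bt_map = {i: t for i, t in enumerate(firsts)}
                for traj in replica_set.trajectories:
                    series = compactness_series(
                        traj, site.coordinating,
                        resolution=max(config.geometry.resolution_ns, traj.dt),
                        site_name=site.name,
                        binding_time=bt_map.get(traj.replica_id),
                    )
                    smooth = running_average(series, window=config.geometry.window_ns)
                    df = series.to_dataframe()
                    df["smoothed_nm"] = smooth.values
                    all_series.append(df)
                    summaries.append(
                        split_pre_post(series, bt_map.get(traj.replica_id))
                    )
                matrix = rmsd_matrix(
                    replica_set, site.coordinating,
                    binding_times=bt_map,
                    stride=config.geometry.rmsd_stride_ns,
                    superpose_pair=config.geometry.pair_superpose,
                )
                emit(matrix.write(out / f"rmsd_{site.name}.txt"))
                bundle.geometry_summaries[site.name] = matrix
            pd.concat(all_series, ignore_index=True).to_csv(
                out / "compactness.csv", index=False, float_format="%.6f"
            )
            emit(out / "compactness.csv")
            sdf = split_summaries_to_dataframe(summaries)
            sdf.to_csv(out / "compactness_summary.csv", index=False, float_format="%.6f")
            emit(out / "compactness_summary.csv")
            bundle.geometry_summaries["splits"] = sdf
            record("geometry", "ok")
        except Exception as exc:
            record("geometry", "failed", f"{type(exc).__name__}: {exc}")
            log.error("geometry failed:\n%s", traceback.format_exc())
    else:
        manifest["stages"]["geometry"] = {
            "status": "skipped", "reason": "no events or no sites",
        }
    timings["geometry"] = time.perf_counter() - t5

    _finalise(bundle, out, timings, t0)
    return bundle


def _finalise(bundle: ReportBundle, out: Path, timings: dict, t_start: float) -> None:
    bundle.manifest["outputs"] = sorted(set(bundle.manifest["outputs"]))
    _json_dump(bundle.manifest, out / "manifest.json")
    _json_dump(
        {k: round(v, 3) for k, v in timings.items()}, out / "timings.json"
    )
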