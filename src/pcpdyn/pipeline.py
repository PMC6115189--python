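"""End-to-end orchestration: simulate -> (rasterize -> measure) -> polarity
-> dynamics -> FRAP -> pulses, with a machine-readable summary.

Every stage communicates through declared files (mesh JSON, trace CSV,
ground-truth JSON, FRAP CSV), so any stage can be re-run from saved
outputs or fed measured data instead of synthetic data.  An identical
config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_model import build_tracks, load_mesh, load_traces, save_mesh, save_traces
from .errors import ConfigurationError, DataValidationError
from .frap_turnover import process_record, records_from_csv, records_to_csv, turnover_vs_behavior
from .imaging_measurement import MeasurementConfig
from .junction_dynamics import (
    cell_reorientation,
    detect_t_transitions,
    length_change_vs_angle,
    rosette_events,
)
from .polarity_stats import build_polarity_table, polarity_report
from .presets import PRESET_NAMES, load_preset
from .pulse_coupling import delta_series, intensity_length_coupling, mean_cross_correlation
from .raster import RasterConfig, measure_stack, rasterize, write_stack
from .synthetic_tissue import (
    SimConfig,
    generate_frap_cohort,
    generate_intensities,
    generate_reorientation_epochs,
    generate_tissue,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "measure", "polarity", "dynamics", "frap", "pulses")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "pcpdyn_run"
    preset: str = "control"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "polarity", "dynamics", "frap", "pulses")
    sim_overrides: dict = field(default_factory=dict)
    # pass-through inputs (skip simulation / use measured data)
    mesh_path: str | None = None
    traces_path: str | None = None
    cytoplasm_path: str | None = None
    frap_path: str | None = None
    # stage parameters
    pixel_size_um: float = 0.2
    line_width_px: int = 3
    window_s: float = 1800.0
    n_frap_records: int = 30
    max_lag_frames: int = 5

    def __post_init__(self) -> None:
        if self.preset not in PRESET_NAMES:
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigurationError(f"unknown stages {bad}; valid: {STAGES}")

    def to_json(self) -> dict:
        doc = dataclasses.asdict(self)
        # the output directory is run metadata, not analysis configuration;
        # leaving it out keeps summaries of identical runs byte-identical
        doc.pop("outdir")
        return doc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).  A stage
    failure aborts with the failing stage named; partial outputs are kept.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pcpdyn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    sim = load_preset(config.preset, seed=config.seed, **config.sim_overrides)
    summary: dict = {
        "version": __version__,
        "preset": config.preset,
        "seed": config.seed,
        "config": config.to_json(),
        "stages": {},
    }
    state: dict = {"sim": sim}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            fn = _STAGE_FUNCS[stage]
            t0 = time.perf_counter()
            logger.info("stage %s: starting", stage)
            try:
                summary["stages"][stage] = fn(config, sim, out, state)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
        (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, sim: SimConfig, out: Path, state: dict) -> dict:
    frames, gt = generate_tissue(sim)
    traces, cyto = generate_intensities(frames, gt, sim)
    early, late = generate_reorientation_epochs(sim)
    save_mesh(frames, out / "mesh.json")
    save_traces(traces, out / "traces.csv")
    cyto.to_csv(out / "cytoplasm.csv", index=False)
    gt.to_json(out / "ground_truth.json")
    save_mesh([early], out / "epoch_early.json")
    save_mesh([late], out / "epoch_late.json")
    state.update(frames=frames, gt=gt, traces=traces, cyto=cyto, epochs=(early, late))
    return {
        "n_cells": gt.n_cells,
        "n_frames": len(frames),
        "n_junction_traces": int(traces["junction_id"].nunique()),
        "n_planted_t1": len(gt.t1_events),
        "n_planted_rosettes": len(gt.rosette_events),
    }


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "frames" not in state:
        if config.mesh_path is None:
            raise ConfigurationError("no mesh available: run simulate or give mesh_path")
        state["frames"] = load_mesh(config.mesh_path)
    if "traces" not in state:
        if config.traces_path is None:
            raise ConfigurationError("no traces available: run simulate/measure or give traces_path")
        state["traces"] = load_traces(config.traces_path)
    if "cyto" not in state and config.cytoplasm_path is not None:
        state["cyto"] = pd.read_csv(config.cytoplasm_path)


def _stage_measure(config: RunConfig, sim: SimConfig, out: Path, state: dict) -> dict:
    if "frames" not in state:
        if config.mesh_path is None:
            raise ConfigurationError("measure needs simulated frames or mesh_path")
        state["frames"] = load_mesh(config.mesh_path)
    if "traces" not in state:
        raise ConfigurationError("measure needs painted intensities (run simulate first)")
    rc = RasterConfig(pixel_size_um=config.pixel_size_um, line_width_px=config.line_width_px)
    stack, meta = rasterize(state["frames"], state["traces"], state["cyto"], rc)
    write_stack(stack, meta, out / "stack.tif")
    mc = MeasurementConfig(line_width_px=config.line_width_px)
    mtraces, mcyto = measure_stack(stack, state["frames"], meta, mc)
    save_traces(mtraces, out / "measured_traces.csv")
    mcyto.to_csv(out / "measured_cytoplasm.csv", index=False)
    state["traces"] = mtraces
    state["cyto"] = mcyto
    return {
        "stack_shape": list(stack.shape),
        "n_measured_junctions": int(mtraces["junction_id"].nunique()),
    }


def _stage_polarity(config: RunConfig, sim: SimConfig, out: Path, state: dict) -> dict:
    _load_inputs(config, state)
    result = {}
    for ch in ("pcp", "myosin"):
        table = build_polarity_table(
            state["traces"], state.get("cyto"), ch, regime_label=config.preset
        )
        table.to_csv(out / f"polarity_{ch}.csv", index=False)
        result[ch] = polarity_report(table)
    (out / "polarity.json").write_text(json.dumps(result, sort_keys=True, indent=1))
    return result


def _stage_dynamics(config: RunConfig, sim: SimConfig, out: Path, state: dict) -> dict:
    _load_inputs(config, state)
    frames = state["frames"]
    tracks = build_tracks(frames, state["traces"], eps_t2_um=sim.eps_t2_um)
    state["tracks"] = tracks
    table, rho, p = length_change_vs_angle(tracks, window_s=config.window_s)
    table.to_csv(out / "length_vs_angle.csv", index=False)
    by_class = {
        "V": float(table.loc[table["mean_angle_deg"] <= 45, "delta_length_um"].mean()),
        "T": float(table.loc[table["mean_angle_deg"] > 45, "delta_length_um"].mean()),
    }
    trans = detect_t_transitions(frames, tracks, eps_t2_um=sim.eps_t2_um)
    pd.DataFrame(
        [
            {"kind": e.kind, "frame": e.frame, "cells": "-".join(map(str, e.cells)),
             "orientation_deg": e.orientation_deg}
            for e in trans.events
        ]
    ).to_csv(out / "transition_events.csv", index=False)
    from .junction_dynamics import contraction_rate

    rates = []
    for tr in tracks:
        if tr.fate == "resolved_T2":
            try:
                rates.append(contraction_rate(tr))
            except Exception:
                pass
    ros = rosette_events(frames)
    rose_rows = [
        {"kind": "formation", "orientation_deg": a} for a in ros.formation_orientations_deg
    ] + [
        {"kind": "resolution", "orientation_deg": a} for a in ros.resolution_orientations_deg
    ]
    pd.DataFrame(rose_rows).to_csv(out / "rosette_orientations.csv", index=False)

    reorient = None
    if "epochs" in state:
        rtable, rsummary = cell_reorientation(*state["epochs"])
        rtable.to_csv(out / "reorientation.csv", index=False)
        reorient = rsummary

    result = {
        "n_tracks": len(tracks),
        "delta_length_rho": rho,
        "delta_length_rho_p": p,
        "mean_delta_length_um": by_class,
        "mean_orientation_drift_deg": float(table["orientation_drift_deg"].mean()),
        "t1_count": trans.t1_count,
        "t2_t3_count": trans.t2_t3_count,
        "rosette_associated_count": trans.rosette_associated_count,
        "n_cells_examined": trans.n_cells_examined,
        "t1_rate_per_cell_per_hr": trans.rate_t1_per_cell_per_hr,
        "mean_contraction_rate_um_per_min": float(np.mean(rates)) if rates else None,
        "rosette_formation_axis": list(ros.formation_axis) if ros.formation_axis else None,
        "rosette_resolution_axis": list(ros.resolution_axis) if ros.resolution_axis else None,
        "reorientation": reorient,
    }
    (out / "dynamics.json").write_text(json.dumps(result, sort_keys=True, indent=1))
    return result


def _stage_frap(config: RunConfig, sim: SimConfig, out: Path, state: dict) -> dict:
    if config.frap_path is not None:
        records = records_from_csv(config.frap_path)
    else:
        records, truth = generate_frap_cohort(sim, config.n_frap_records)
        records_to_csv(records, out / "frap_input.csv")
    for rec in records:
        process_record(rec)
    res = turnover_vs_behavior(records)
    res.table.to_csv(out / "frap_fits.csv", index=False)
    curve_rows = []
    for cls, cur in res.group_curves.items():
        for i, t in enumerate(res.group_time_s):
            curve_rows.append(
                {"shrink_class": cls, "time_s": t, "mean": cur["mean"][i],
                 "sem": cur["sem"][i], "n": int(cur["n"][i])}
            )
    pd.DataFrame(curve_rows).to_csv(out / "frap_group_curves.csv", index=False)
    by_class = res.table.groupby("shrink_class")["nonmobile_fraction"].mean().to_dict()
    return {
        "n_records": len(records),
        "nonmobile_by_class": {k: float(v) for k, v in by_class.items()},
        "regression_slope_per_um": res.regression_slope,
        "spearman_rho": res.spearman_rho,
        "spearman_p": res.spearman_p,
    }


def _stage_pulses(config: RunConfig, sim: SimConfig, out: Path, state: dict) -> dict:
    _load_inputs(config, state)
    if "tracks" not in state:
        state["tracks"] = build_tracks(state["frames"], state["traces"], eps_t2_um=sim.eps_t2_um)
    tracks = state["tracks"]
    min_frames = 2 * config.max_lag_frames + 4
    pairs = []
    for tr in tracks:
        if tr.n_frames < min_frames:
            continue
        pcp = tr.intensity_series.get("pcp")
        myo = tr.intensity_series.get("myosin")
        if pcp is None or myo is None or np.any(np.isnan(pcp)) or np.any(np.isnan(myo)):
            continue
        pairs.append(
            (
                delta_series(pcp, tr.times_s, junction_id=str(tr.junction_id), channel="pcp"),
                delta_series(myo, tr.times_s, junction_id=str(tr.junction_id), channel="myosin"),
            )
        )
    curve = mean_cross_correlation(pairs, max_lag_frames=config.max_lag_frames)
    curve.to_csv(out / "cross_correlation.csv", index=False)
    try:
        coupling_table, c_rho, c_p = intensity_length_coupling(tracks, "pcp")
        coupling_table.to_csv(out / "intensity_length_coupling.csv", index=False)
    except DataValidationError as exc:
        # e.g. a regime whose junction lengths never change: the coupling
        # correlation is undefined, which is a result, not a failure
        logger.warning("intensity/length coupling unavailable: %s", exc)
        c_rho, c_p = None, None
    peak = curve.loc[curve["mean_rho"].idxmax()]
    return {
        "n_junctions": int(curve["n"].iloc[0]),
        "zero_lag_mean_rho": float(curve.loc[curve["lag_frames"] == 0, "mean_rho"].iloc[0]),
        "peak_lag_frames": int(peak["lag_frames"]),
        "peak_mean_rho": float(peak["mean_rho"]),
        "pcp_length_coupling_rho": c_rho,
        "pcp_length_coupling_p": c_p,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "measure": _stage_measure,
    "polarity": _stage_polarity,
    "dynamics": _stage_dynamics,
    "frap": _stage_frap,
    "pulses": _stage_pulses,
}
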