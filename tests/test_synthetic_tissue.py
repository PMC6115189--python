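"""Ground-truth generator: determinism, topology, planted events/signals."""

import json

import numpy as np
import pytest

from pcpdyn.core_model import parse_junction_id, save_mesh
from pcpdyn.errors import ConfigurationError
from pcpdyn.frap_turnover import normalize_recovery
from pcpdyn.synthetic_tissue import (
    SimConfig,
    generate_frap,
    generate_intensities,
    generate_reorientation_epochs,
    generate_tissue,
)


def test_identical_seed_bit_identical_output(tmp_path):
    cfg = SimConfig(n_cells=25, n_frames=14, seed=5)
    out = []
    for name in ("a", "b"):
        frames, gt = generate_tissue(cfg)
        traces, cyto = generate_intensities(frames, gt, cfg)
        p = tmp_path / f"{name}.json"
        save_mesh(frames, p)
        traces.to_csv(tmp_path / f"{name}.csv", index=False)
        out.append((p.read_bytes(), (tmp_path / f"{name}.csv").read_bytes()))
    assert out[0] == out[1]


def test_topology_valid_every_frame(control_sim):
    _, frames, _, _, _ = control_sim
    for f in frames:
        f.validate()  # simple polygons, Euler relation, unique junction ids


def test_cell_count_conserved_across_events(control_sim):
    _, frames, gt, _, _ = control_sim
    assert len(gt.t1_events) > 0 and len(gt.rosette_events) > 0
    counts = {len(f.cells) for f in frames}
    assert counts == {gt.n_cells}


def test_no_events_means_static_adjacency():
    cfg = SimConfig(n_cells=25, n_frames=6, n_t1_events=0, n_rosettes=0, seed=3)
    frames, gt = generate_tissue(cfg)
    assert gt.t1_events == [] and gt.rosette_events == []
    assert frames[0].adjacency() == frames[-1].adjacency()


def test_planted_events_match_bruteforce_adjacency_diff(control_sim):
    """Ground-truth bookkeeping equals a brute-force diff of the first and
    last adjacency sets (the T1 signature: quartet pair swap)."""
    _, frames, gt, _, _ = control_sim
    lost = frames[0].adjacency() - frames[-1].adjacency()
    gained = frames[-1].adjacency() - frames[0].adjacency()
    expect_lost = {tuple(ev["pair"]) for ev in gt.t1_events}
    expect_gained = {tuple(ev["new_pair"]) for ev in gt.t1_events}
    for ros in gt.rosette_events:
        expect_lost.update(tuple(p) for p in ros["pairs"])
        expect_gained.add(tuple(ros["new_pair"]))
    assert lost == expect_lost
    assert gained == expect_gained


def test_t1_contraction_is_linear_to_subresolution(control_sim):
    cfg, frames, gt, _, _ = control_sim
    ev = gt.t1_events[0]
    pair = tuple(ev["pair"])
    lengths = []
    for f in frames[ev["start_frame"]: ev["swap_frame"]]:
        lengths.append(f.junction_map()[pair].length_um)
    assert lengths[-1] < cfg.eps_t2_um  # fully contracted before the swap
    diffs = np.diff(lengths[:-1])
    assert np.all(diffs < 0)
    assert np.std(diffs) / abs(np.mean(diffs)) < 0.05  # near-constant rate


def test_infeasible_event_schedule_raises():
    with pytest.raises(ConfigurationError):
        generate_tissue(SimConfig(n_cells=9, n_frames=10, n_t1_events=40, seed=0))


def test_intensities_constant_without_dynamics(static_sim):
    """noise 0, no flow/events: with pulses and coupling silenced the PCP
    trace is exactly its planted class baseline in every frame."""
    cfg, frames, gt, _, _ = static_sim
    quiet = SimConfig(
        n_cells=cfg.n_cells, n_frames=cfg.n_frames, seed=cfg.seed,
        convergence_rate_per_s=0.0, n_t1_events=0, n_rosettes=0,
        noise_sd=0.0, pulse_amplitude=0.0, intensity_length_coupling=0.0,
    )
    traces, _ = generate_intensities(frames, gt, quiet)
    pcp = traces[traces.channel == "pcp"]
    for jid, grp in pcp.groupby("junction_id"):
        vals = grp["mean_intensity"].to_numpy()
        assert np.all(vals == vals[0])
        expected = gt.junction_enrichment[jid] * quiet.cytoplasm_baseline
        assert vals[0] == pytest.approx(expected, abs=1e-12)


def test_perfect_coupling_makes_delta_series_proportional(static_sim):
    cfg, frames, gt, _, _ = static_sim
    coupled = SimConfig(
        n_cells=cfg.n_cells, n_frames=cfg.n_frames, seed=cfg.seed,
        convergence_rate_per_s=0.0, n_t1_events=0, n_rosettes=0,
        noise_sd=0.0, intensity_length_coupling=0.0,
        pulse_coupling_rho=1.0, pulse_lag_frames=0,
    )
    traces, _ = generate_intensities(frames, gt, coupled)
    jid = traces["junction_id"].iloc[0]
    sub = traces[traces.junction_id == jid]
    pcp = sub[sub.channel == "pcp"].sort_values("frame")["mean_intensity"].to_numpy()
    myo = sub[sub.channel == "myosin"].sort_values("frame")["mean_intensity"].to_numpy()
    assert np.allclose(np.diff(pcp), np.diff(myo), atol=1e-9)


def test_planted_zero_lag_correlation_recovered_monte_carlo():
    """Empirical zero-lag delta-series correlation across many junctions
    approaches the planted rho."""
    cfg = SimConfig(
        n_cells=36, n_frames=60, seed=21, convergence_rate_per_s=0.0,
        n_t1_events=0, n_rosettes=0, noise_sd=0.0,
        intensity_length_coupling=0.0, pulse_coupling_rho=0.6,
    )
    frames, gt = generate_tissue(cfg)
    traces, _ = generate_intensities(frames, gt, cfg)
    rhos = []
    for jid, sub in traces.groupby("junction_id"):
        pcp = sub[sub.channel == "pcp"].sort_values("frame")["mean_intensity"].to_numpy()
        myo = sub[sub.channel == "myosin"].sort_values("frame")["mean_intensity"].to_numpy()
        rhos.append(np.corrcoef(np.diff(pcp), np.diff(myo))[0, 1])
    assert np.mean(rhos) == pytest.approx(0.6, abs=0.05)


# ---------------------------------------------------------------------------
# FRAP generator
# ---------------------------------------------------------------------------

def test_frap_closed_form_value_at_tau():
    cfg = SimConfig(frap_noise_sd=0.0, frap_photofade_per_s=0.0, seed=2)
    rec = generate_frap(cfg, mobile_fraction=0.6, tau_s=20.0)
    norm = normalize_recovery(
        rec.bleach_trace, rec.reference_trace, rec.background_trace,
        rec.times_s, rec.t_bleach_s,
    )
    floor = cfg.frap_bleach_floor
    i = int(np.argmin(np.abs(rec.times_s - (rec.t_bleach_s + 20.0))))
    expected = floor + 0.6 * (1.0 - floor) * (1.0 - np.exp(-1.0))
    assert norm[i] == pytest.approx(expected, abs=1e-9)
    # pre-bleach level pinned at 1, drop to the planted floor at the bleach frame
    assert norm[rec.times_s < rec.t_bleach_s] == pytest.approx(1.0, abs=1e-9)
    assert norm[rec.times_s >= rec.t_bleach_s][0] == pytest.approx(floor, abs=1e-9)


def test_frap_full_instant_recovery():
    cfg = SimConfig(frap_noise_sd=0.0, frap_photofade_per_s=0.0, seed=2)
    rec = generate_frap(cfg, mobile_fraction=1.0, tau_s=1e-6)
    norm = normalize_recovery(
        rec.bleach_trace, rec.reference_trace, rec.background_trace,
        rec.times_s, rec.t_bleach_s,
    )
    assert norm[-1] == pytest.approx(1.0, abs=1e-9)


def test_frap_bleach_at_final_frame_rejected():
    cfg = SimConfig(frap_total_s=0.0, seed=2)
    with pytest.raises(ConfigurationError):
        generate_frap(cfg)


# ---------------------------------------------------------------------------
# reorientation epochs
# ---------------------------------------------------------------------------

def test_reorientation_epochs_follow_regime():
    ml = SimConfig(n_cells=36, reorientation="ml", seed=4)
    early, late = generate_reorientation_epochs(ml)
    early_angles = np.array([c.long_axis_angle_deg for c in early.cells])
    late_angles = np.array([c.long_axis_angle_deg for c in late.cells])
    assert np.nanmean(early_angles) > 60.0  # AP-aligned at the early stage
    assert np.nanmean(late_angles) < 30.0  # reoriented toward ML
    none = SimConfig(n_cells=36, reorientation="none", seed=4)
    _, late_none = generate_reorientation_epochs(none)
    late_none_angles = np.array([c.long_axis_angle_deg for c in late_none.cells])
    assert np.nanmean(late_none_angles) > 60.0  # stays AP-aligned


def test_ground_truth_json_round_trip(tmp_path, control_sim):
    _, _, gt, _, _ = control_sim
    p = tmp_path / "gt.json"
    gt.to_json(p)
    doc = json.loads(p.read_text())
    assert doc["n_cells"] == gt.n_cells
    assert len(doc["t1_events"]) == len(gt.t1_events)
    for key, cls in doc["junction_class"].items():
        parse_junction_id(key)  # well-formed ids
        assert cls in ("V", "T")
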