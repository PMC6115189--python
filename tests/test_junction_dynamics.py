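"""Junction behavior: length change vs angle, T transitions, rosettes,
contraction rates and cell reorientation."""

import numpy as np
import pytest

from pcpdyn.core_model import JunctionTrack, build_tracks
from pcpdyn.errors import DataValidationError
from pcpdyn.junction_dynamics import (
    cell_reorientation,
    contraction_rate,
    detect_t_transitions,
    length_change_vs_angle,
    rosette_events,
)
from pcpdyn.synthetic_tissue import (
    SimConfig,
    generate_reorientation_epochs,
    generate_tissue,
)


def _track(times, lengths, fate="resolved_T2", angles=None):
    n = len(times)
    return JunctionTrack(
        junction_id=(0, 1),
        frames=np.arange(n),
        times_s=np.asarray(times, dtype=float),
        length_series=np.asarray(lengths, dtype=float),
        angle_series=np.zeros(n) if angles is None else np.asarray(angles, float),
        fate=fate,
    )


# ---------------------------------------------------------------------------
# length change vs angle
# ---------------------------------------------------------------------------

def test_control_v_shrinks_t_grows(control_tracks):
    table, rho, p = length_change_vs_angle(control_tracks)
    v = table.loc[table.mean_angle_deg <= 45, "delta_length_um"]
    t = table.loc[table.mean_angle_deg > 45, "delta_length_um"]
    assert v.mean() < 0 < t.mean()
    assert rho > 0.3 and p < 1e-6


def test_static_tissue_all_zero_delta(static_sim):
    _, frames, _, _, _ = static_sim
    tracks = build_tracks(frames)
    table, rho, _ = length_change_vs_angle(tracks)
    assert np.allclose(table["delta_length_um"], 0.0)
    assert np.isnan(rho)  # correlation undefined on constant delta


def test_unpolarized_regime_correlation_near_zero():
    cfg = SimConfig(
        n_cells=64, n_frames=20, seed=17, convergence_rate_per_s=0.0,
        shrink_bias=0.5, n_t1_events=4, n_rosettes=0,
    )
    frames, _ = generate_tissue(cfg)
    tracks = build_tracks(frames)
    _, rho, p = length_change_vs_angle(tracks)
    assert abs(rho) < 0.25


def test_orientation_drift_is_small(control_tracks):
    table, _, _ = length_change_vs_angle(control_tracks)
    persisting = table[table.fate == "persists"]
    # junctions stay orientation-stable on average; only junctions abutting
    # an intercalation event reorient appreciably
    assert persisting["orientation_drift_deg"].mean() < 5.0
    assert persisting["orientation_drift_deg"].median() < 2.0


# ---------------------------------------------------------------------------
# T transitions
# ---------------------------------------------------------------------------

def test_detector_recall_precision_on_planted_mesh():
    cfg = SimConfig(n_cells=49, n_frames=25, seed=23, n_t1_events=5,
                    n_rosettes=0, noise_sd=0.0)
    frames, gt = generate_tissue(cfg)
    tracks = build_tracks(frames, eps_t2_um=cfg.eps_t2_um)
    res = detect_t_transitions(frames, tracks, eps_t2_um=cfg.eps_t2_um)
    detected = {(tuple(sorted(e.cells)), e.frame) for e in res.events if e.kind == "T1_T2"}
    planted = {(tuple(ev["pair"]), ev["swap_frame"]) for ev in gt.t1_events}
    assert len(detected) == len(planted) == 5
    for cells, frame in planted:
        match = [d for d in detected if d[0] == cells and abs(d[1] - frame) <= 1]
        assert len(match) == 1
    # every T1 finds its perpendicular partner junction
    assert res.t2_t3_count == 5


def test_rate_arithmetic_five_events_twenty_cells_two_hours():
    cfg = SimConfig(
        n_cells=20, n_frames=31, dt_s=240.0, seed=29, n_t1_events=5,
        n_rosettes=0, convergence_rate_per_s=0.0,
    )
    frames, gt = generate_tissue(cfg)
    assert (frames[-1].time_s - frames[0].time_s) == pytest.approx(7200.0)
    tracks = build_tracks(frames, eps_t2_um=cfg.eps_t2_um)
    res = detect_t_transitions(frames, tracks, eps_t2_um=cfg.eps_t2_um)
    assert res.t1_count == 5 and res.n_cells_examined == 20
    assert res.rate_t1_per_cell_per_hr == pytest.approx(0.125)


def test_rosette_mediated_losses_counted_separately(control_sim, control_tracks):
    cfg, frames, gt, _, _ = control_sim
    res = detect_t_transitions(frames, control_tracks, eps_t2_um=cfg.eps_t2_um)
    assert res.t1_count == len(gt.t1_events)
    assert res.rosette_associated_count == 2 * len(gt.rosette_events)


def test_no_events_zero_rate(static_sim):
    _, frames, _, _, _ = static_sim
    tracks = build_tracks(frames)
    res = detect_t_transitions(frames, tracks)
    assert res.t1_count == 0 and res.rate_t1_per_cell_per_hr == 0.0


# ---------------------------------------------------------------------------
# contraction rate
# ---------------------------------------------------------------------------

def test_contraction_rate_exact_on_linear_track():
    t = np.arange(0, 300, 20.0)
    rate = contraction_rate(_track(t, 10.0 - 0.01 * t))
    assert rate == pytest.approx(0.6, abs=1e-9)  # 0.01 um/s = 0.6 um/min


def test_contraction_rate_time_origin_invariant():
    t = np.arange(0, 300, 20.0)
    r0 = contraction_rate(_track(t, 10.0 - 0.01 * t))
    r1 = contraction_rate(_track(t + 5000.0, 10.0 - 0.01 * t))
    assert r1 == pytest.approx(r0, abs=1e-9)


def test_contraction_rate_constant_track_is_zero():
    t = np.arange(0, 200, 20.0)
    assert contraction_rate(_track(t, np.full(len(t), 0.1))) == pytest.approx(0.0, abs=1e-12)


def test_contraction_rate_noisy_track_within_ten_percent(rng):
    t = np.arange(30) * 10.0
    planted = 0.3  # um/min; declines from 1.5 um to below the T2 threshold
    lengths = 1.5 - planted / 60.0 * t + rng.normal(0, 0.05, 30)
    rate = contraction_rate(_track(t, lengths), window=(0, 29))
    assert rate == pytest.approx(planted, rel=0.1)


def test_contraction_rate_requires_resolved_fate_and_enough_frames():
    t = np.arange(0, 100, 20.0)
    with pytest.raises(DataValidationError):
        contraction_rate(_track(t, 10 - 0.01 * t, fate="persists"))
    with pytest.raises(DataValidationError):
        contraction_rate(_track(t, 10 - 0.01 * t), window=(4, 4))


# ---------------------------------------------------------------------------
# rosettes
# ---------------------------------------------------------------------------

def test_rosette_detection_recovers_planted_axes():
    cfg = SimConfig(n_cells=100, n_frames=25, seed=31, n_t1_events=0,
                    n_rosettes=5, noise_sd=0.0)
    frames, gt = generate_tissue(cfg)
    res = rosette_events(frames)
    assert len(res.formation_orientations_deg) == 2 * len(gt.rosette_events)
    assert len(res.resolution_orientations_deg) == len(gt.rosette_events)
    f_mean, f_r = res.formation_axis
    r_mean, r_r = res.resolution_axis
    assert min(f_mean, 90 - abs(f_mean - 90)) < 10.0  # ML-oriented formations
    assert f_r > 0.9
    assert r_mean == pytest.approx(90.0, abs=5.0)  # AP-oriented resolutions
    assert r_r > 0.9


def test_rosette_empty_event_list_allowed(static_sim):
    _, frames, _, _, _ = static_sim
    res = rosette_events(frames)
    assert res.events == [] and res.formation_axis is None


# ---------------------------------------------------------------------------
# cell reorientation
# ---------------------------------------------------------------------------

def test_reorientation_control_majority_toward_ml():
    cfg = SimConfig(n_cells=100, reorientation="ml", seed=37)
    early, late = generate_reorientation_epochs(cfg)
    table, summary = cell_reorientation(early, late)
    assert summary["fraction_toward_ml"] > 0.8
    assert summary["mean_delta_deg"] < -30
    assert summary["wilcoxon_p"] < 1e-6


def test_reorientation_disrupted_regime_is_balanced():
    cfg = SimConfig(n_cells=100, reorientation="none", seed=37)
    early, late = generate_reorientation_epochs(cfg)
    _, summary = cell_reorientation(early, late)
    assert 0.25 < summary["fraction_toward_ml"] < 0.75
    assert abs(summary["mean_delta_deg"]) < 5.0


def test_reorientation_identical_epochs_all_zero():
    cfg = SimConfig(n_cells=36, reorientation="ml", seed=41)
    early, _ = generate_reorientation_epochs(cfg)
    table, summary = cell_reorientation(early, early)
    assert np.allclose(table["angle_late_deg"] - table["angle_early_deg"], 0.0)
    assert summary["wilcoxon_p"] == 1.0


def test_reorientation_requires_shared_cells():
    cfg = SimConfig(n_cells=36, seed=43)
    early, late = generate_reorientation_epochs(cfg)
    from dataclasses import replace

    relabeled = replace(
        late, cells=[replace(c, cell_id=c.cell_id + 10000) for c in late.cells]
    )
    with pytest.raises(DataValidationError):
        cell_reorientation(early, relabeled)
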