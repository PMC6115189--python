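"""Junction-behavior quantification.

Covers the intercalation phenotype readouts: junction length change versus
orientation, detection of T transitions (T1-T2 junction loss and the
perpendicular T2-T3 gain) with per-cell-per-hour rates, contraction-rate
estimation for completed T1-T2 transitions, multicellular rosette
formation/resolution with axial circular statistics, and paired cell
long-axis reorientation between developmental epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circular import axial_mean_resultant
from .core_model import EPS_T2_UM, JunctionTrack, TissueFrame
from .errors import DataValidationError

__all__ = [
    "ROSETTE_MIN_CELLS",
    "TransitionEvent",
    "length_change_vs_angle",
    "detect_t_transitions",
    "contraction_rate",
    "rosette_events",
    "cell_reorientation",
]

#: minimum number of cells meeting at one vertex to call a rosette
#: (the standard criterion in the intercalation literature)
ROSETTE_MIN_CELLS = 5


@dataclass
class TransitionEvent:
    kind: str  # 'T1_T2' | 'T2_T3' | 'rosette_formation' | 'rosette_resolution'
    frame: int
    cells: tuple[int, ...]
    orientation_deg: float | None = None
    contraction_window: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# length change vs orientation
# ---------------------------------------------------------------------------

def length_change_vs_angle(
    tracks: Sequence[JunctionTrack], window_s: float = 1800.0
) -> tuple[pd.DataFrame, float, float]:
    """Per-track (axial mean angle, delta L) over a time window, plus
    Spearman rho between them.

    The default 1800 s window matches the measurement interval used for the
    ensemble angle-vs-length-change analysis.  Tracks shorter than the
    window contribute their full span and are flagged.  The table also
    reports per-track orientation drift (max - min of the angle series) to
    support orientation-stability statements.
    """
    if not tracks:
        raise DataValidationError("no tracks given")
    rows = []
    for tr in tracks:
        t0 = tr.times_s[0]
        in_window = tr.times_s <= t0 + window_s
        idx = np.nonzero(in_window)[0]
        full_span = tr.times_s[-1] - t0 >= window_s
        k_end = idx[-1]
        rows.append(
            {
                "junction_id": f"{tr.junction_id[0]}-{tr.junction_id[1]}",
                "mean_angle_deg": float(
                    axial_mean_resultant(tr.angle_series[: k_end + 1])[0]
                ),
                "delta_length_um": float(tr.length_series[k_end] - tr.length_series[0]),
                "orientation_drift_deg": float(
                    np.max(tr.angle_series[: k_end + 1]) - np.min(tr.angle_series[: k_end + 1])
                ),
                "spans_window": bool(full_span),
                "fate": tr.fate,
            }
        )
    table = pd.DataFrame(rows)
    if (
        table["mean_angle_deg"].nunique() < 2
        or table["delta_length_um"].nunique() < 2
    ):
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(table["mean_angle_deg"], table["delta_length_um"])
    return table, float(rho), float(p)


# ---------------------------------------------------------------------------
# T transitions
# ---------------------------------------------------------------------------

@dataclass
class TransitionSummary:
    events: list[TransitionEvent]
    t1_count: int
    t2_t3_count: int
    rosette_associated_count: int
    n_cells_examined: int
    duration_hr: float
    rate_t1_per_cell_per_hr: float
    rate_t2_t3_per_cell_per_hr: float


def _cells_examined(frames: Sequence[TissueFrame]) -> int:
    """Cells present in the field for at least half of the frames."""
    counts: dict[int, int] = {}
    for f in frames:
        for c in f.cells:
            counts[c.cell_id] = counts.get(c.cell_id, 0) + 1
    need = len(frames) / 2.0
    return sum(1 for v in counts.values() if v >= need)


def detect_t_transitions(
    frames: Sequence[TissueFrame],
    tracks: Sequence[JunctionTrack],
    *,
    eps_t2_um: float = EPS_T2_UM,
    rosette_min_cells: int = ROSETTE_MIN_CELLS,
    t2_t3_max_delay_frames: int = 2,
) -> TransitionSummary:
    """Detect T1-T2 / T2-T3 transitions and express them as rates.

    A T1-T2 event is a track that disappears mid-movie with final length
    below the T2 threshold, provided its cells do not merge into a
    rosette-scale vertex (rosette-mediated exchanges are counted
    separately).  The matching T2-T3 event is the appearance of a junction
    between the two *lateral* cells of the resolved junction's quartet (the
    third cells at its two endpoints just before resolution); unrelated
    adjacency gains are not counted.  The headline rate is
    T1-T2 count / (duration_hr * n_cells_examined).
    """
    if len(frames) < 2:
        raise DataValidationError("need >= 2 frames to detect transitions")
    frame_by_index = {f.frame_index: f for f in frames}
    order = sorted(frame_by_index)
    incident_cache: dict[int, dict[int, set[int]]] = {}

    def incident(fi: int) -> dict[int, set[int]]:
        if fi not in incident_cache:
            incident_cache[fi] = frame_by_index[fi].vertex_incident_cells()
        return incident_cache[fi]

    events: list[TransitionEvent] = []
    rosette_assoc = 0
    t2_count = 0
    last_frame = order[-1]
    for tr in tracks:
        if tr.fate != "resolved_T2":
            continue
        end_fi = int(tr.frames[-1])
        if end_fi >= last_frame:
            continue
        a, b = tr.junction_id
        pos = order.index(end_fi)
        next_fi = order[pos + 1]
        # rosette-associated if the pair still shares a rosette-scale vertex
        inc_next = incident(next_fi)
        shared_rosette = any(
            {a, b} <= cells and len(cells) >= rosette_min_cells
            for cells in inc_next.values()
        )
        if shared_rosette:
            rosette_assoc += 1
            continue
        # lateral quartet cells from the last frame the junction existed
        fr_end = frame_by_index[end_fi]
        jm = fr_end.junction_map()
        j = jm.get((min(a, b), max(a, b)))
        lateral: tuple[int, int] | None = None
        if j is not None:
            inc_end = incident(end_fi)
            thirds = []
            for vid in (j.vertex_ids[0], j.vertex_ids[-1]):
                extra = inc_end.get(vid, set()) - {a, b}
                if len(extra) == 1:
                    thirds.append(extra.pop())
            if len(thirds) == 2 and thirds[0] != thirds[1]:
                lateral = (min(thirds), max(thirds))
        events.append(
            TransitionEvent(
                kind="T1_T2", frame=end_fi, cells=(a, b),
                orientation_deg=float(tr.angle_series[-1]),
                contraction_window=_contraction_window(tr),
            )
        )
        # look for the perpendicular gain among the lateral pair
        if lateral is not None:
            for look in order[pos + 1: pos + 1 + t2_t3_max_delay_frames]:
                adj = frame_by_index[look].adjacency()
                prev_adj = frame_by_index[end_fi].adjacency()
                if lateral in adj and lateral not in prev_adj:
                    jn = frame_by_index[look].junction_map().get(lateral)
                    events.append(
                        TransitionEvent(
                            kind="T2_T3", frame=look, cells=lateral,
                            orientation_deg=None if jn is None else jn.angle_deg,
                        )
                    )
                    t2_count += 1
                    break

    n_cells = _cells_examined(frames)
    t0 = frame_by_index[order[0]].time_s
    t1 = frame_by_index[order[-1]].time_s
    duration_hr = (t1 - t0) / 3600.0
    t1_count = sum(1 for e in events if e.kind == "T1_T2")
    denom = duration_hr * n_cells
    return TransitionSummary(
        events=events,
        t1_count=t1_count,
        t2_t3_count=t2_count,
        rosette_associated_count=rosette_assoc,
        n_cells_examined=n_cells,
        duration_hr=duration_hr,
        rate_t1_per_cell_per_hr=t1_count / denom if denom > 0 else float("nan"),
        rate_t2_t3_per_cell_per_hr=t2_count / denom if denom > 0 else float("nan"),
    )


def _contraction_window(track: JunctionTrack, rel_tol: float = 0.05) -> tuple[int, int]:
    """(start_frame, end_frame) of the contraction fit window: from the last
    frame where the length is within ``rel_tol`` of its running maximum
    before the monotone decline, to the final (T2) frame."""
    lengths = track.length_series
    runmax = np.maximum.accumulate(lengths)
    near_max = lengths >= (1.0 - rel_tol) * runmax
    start = int(np.nonzero(near_max)[0][-1])
    start = max(0, min(start, len(lengths) - 3))  # keep >= 3 fit points
    return int(track.frames[start]), int(track.frames[-1])


def contraction_rate(track: JunctionTrack, window: tuple[int, int] | None = None) -> float:
    """Contraction rate (um/min) of a completed T1-T2 transition.

    Least-squares linear fit of L(t) on the contraction window (default:
    from the last pre-decline maximum to the T2 frame); returns the negated
    slope so contracting junctions are positive.
    """
    if track.fate != "resolved_T2":
        raise DataValidationError("contraction rate is defined for resolved_T2 tracks")
    if window is None:
        window = _contraction_window(track)
    lo, hi = window
    mask = (track.frames >= lo) & (track.frames <= hi)
    if mask.sum() < 3:
        raise DataValidationError(
            f"contraction window [{lo}, {hi}] has fewer than 3 frames"
        )
    t = track.times_s[mask]
    y = track.length_series[mask]
    slope = np.polyfit(t - t[0], y, 1)[0]
    return float(-slope * 60.0)


# ---------------------------------------------------------------------------
# rosettes
# ---------------------------------------------------------------------------

@dataclass
class RosetteSummary:
    events: list[TransitionEvent]
    formation_orientations_deg: list[float]
    resolution_orientations_deg: list[float]
    formation_axis: tuple[float, float] | None  # (mean_deg, R)
    resolution_axis: tuple[float, float] | None


def rosette_events(
    frames: Sequence[TissueFrame], *, rosette_min_cells: int = ROSETTE_MIN_CELLS
) -> RosetteSummary:
    """Rosette formation/resolution events and their axial orientations.

    Formation: a vertex gains >= ``rosette_min_cells`` incident cells; the
    orientation samples are the angles of the junctions (within the rosette
    cell set) that vanished at that frame.  Resolution: a new junction
    appears between two cells of an existing rosette; its angle is the
    resolution orientation.  Axial means use the double-angle transform.
    """
    if len(frames) < 2:
        raise DataValidationError("need >= 2 frames to detect rosettes")
    events: list[TransitionEvent] = []
    formations: list[float] = []
    resolutions: list[float] = []

    def rosette_sets(f: TissueFrame) -> set[frozenset]:
        return {
            frozenset(cells)
            for cells in f.vertex_incident_cells().values()
            if len(cells) >= rosette_min_cells
        }

    prev = frames[0]
    prev_rosettes = rosette_sets(prev)
    for cur in frames[1:]:
        cur_rosettes = rosette_sets(cur)
        prev_map = prev.junction_map()
        cur_map = cur.junction_map()
        # formations
        for ros in cur_rosettes - prev_rosettes:
            angles = [
                j.angle_deg
                for jid, j in prev_map.items()
                if jid not in cur_map and set(jid) <= ros
            ]
            for ang in angles:
                formations.append(float(ang))
            events.append(
                TransitionEvent(
                    kind="rosette_formation", frame=cur.frame_index,
                    cells=tuple(sorted(ros)),
                    orientation_deg=float(np.mean(angles)) if angles else None,
                )
            )
        # resolutions: new junction inside a rosette present in the previous frame
        for ros in prev_rosettes:
            for jid, j in cur_map.items():
                if jid not in prev_map and set(jid) <= ros:
                    resolutions.append(float(j.angle_deg))
                    events.append(
                        TransitionEvent(
                            kind="rosette_resolution", frame=cur.frame_index,
                            cells=jid, orientation_deg=float(j.angle_deg),
                        )
                    )
        prev, prev_rosettes = cur, cur_rosettes

    form_axis = axial_mean_resultant(np.array(formations)) if formations else None
    res_axis = axial_mean_resultant(np.array(resolutions)) if resolutions else None
    return RosetteSummary(
        events=events,
        formation_orientations_deg=formations,
        resolution_orientations_deg=resolutions,
        formation_axis=form_axis,
        resolution_axis=res_axis,
    )


# ---------------------------------------------------------------------------
# cell reorientation
# ---------------------------------------------------------------------------

def cell_reorientation(
    frames_early: Sequence[TissueFrame] | TissueFrame,
    frames_late: Sequence[TissueFrame] | TissueFrame,
) -> tuple[pd.DataFrame, dict]:
    """Paired cell long-axis angles at two developmental epochs.

    Per cell: the (axial-mean) long-axis angle in each epoch.  The summary
    reports the fraction of cells whose angle decreased (reoriented toward
    the mediolateral axis) and a paired Wilcoxon signed-rank p-value.
    """
    early = [frames_early] if isinstance(frames_early, TissueFrame) else list(frames_early)
    late = [frames_late] if isinstance(frames_late, TissueFrame) else list(frames_late)

    def epoch_angles(fr: list[TissueFrame]) -> dict[int, float]:
        per_cell: dict[int, list[float]] = {}
        for f in fr:
            for c in f.cells:
                if not np.isnan(c.long_axis_angle_deg):
                    per_cell.setdefault(c.cell_id, []).append(c.long_axis_angle_deg)
        return {
            cid: axial_mean_resultant(np.array(v))[0] for cid, v in per_cell.items()
        }

    ae = epoch_angles(early)
    al = epoch_angles(late)
    shared = sorted(set(ae) & set(al))
    if not shared:
        raise DataValidationError("no cells shared between the two epochs")
    table = pd.DataFrame(
        {
            "cell_id": shared,
            "angle_early_deg": [ae[c] for c in shared],
            "angle_late_deg": [al[c] for c in shared],
        }
    )
    delta = table["angle_late_deg"] - table["angle_early_deg"]
    toward_ml = float((delta < 0).mean())
    if np.allclose(delta, 0.0):
        p = 1.0
    else:
        _, p = stats.wilcoxon(delta)
    summary = {
        "n_cells": len(shared),
        "fraction_toward_ml": toward_ml,
        "mean_delta_deg": float(delta.mean()),
        "wilcoxon_p": float(p),
    }
    return table, summary
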