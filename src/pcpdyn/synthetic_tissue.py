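"""Ground-truth synthetic tissue, intensity and FRAP generator.

The generator emulates the study system — a convergently extending
neural-plate epithelium — as a *kinematic* polygonal sheet: a vertex-jittered
brick-wall tessellation (valence-3 vertices, topologically equivalent to a
relaxed polygonal epithelium) whose mediolaterally oriented (V) junctions
preferentially contract under a global convergence flow, with scheduled T1
neighbor exchanges and multicellular rosette events executed as explicit
topological operations.  Contraction schedules are prescribed rather than
emergent from force balance: the purpose of the module is controlled ground
truth for the analysis stages, not mechanics.

Planted quantities (all recorded in :class:`SyntheticGroundTruth`):

* per-class PCP and myosin enrichment ratios,
* the coupling coefficient kappa between shrink velocity and PCP intensity,
* the zero-lag correlation rho and lag of the PCP/myosin pulse delta-series,
* T1 and rosette events (cells, frames, orientations),
* FRAP mobile fractions and recovery time constants.

Determinism: every public generator derives its RNG stream from
``SimConfig.seed`` via fixed ``SeedSequence`` spawn keys, so an identical
config yields bit-identical output.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShPoly

from .core_model import (
    EPS_T2_UM,
    TissueFrame,
    classify_junction,
    junction_id_str,
)
from .errors import ConfigurationError, DataValidationError
from .frap_turnover import FrapRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SyntheticGroundTruth",
    "generate_tissue",
    "generate_intensities",
    "generate_frap",
    "generate_frap_cohort",
    "generate_reorientation_epochs",
]

_STREAM_GEOMETRY = 0
_STREAM_INTENSITY = 1
_STREAM_FRAP = 2
_STREAM_EPOCHS = 3


def _rng(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(purpose,)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All knobs of the synthetic study system.

    Units: lengths um, times s, rates as named.  Intensities are in
    "normalized units" with the cytoplasmic baseline at 1.0, so a junction
    painted at 2.0 has a planted cytoplasm-enrichment ratio of 2.0.
    """

    n_cells: int = 100
    n_frames: int = 31
    dt_s: float = 20.0

    # geometry
    cell_width_um: float = 10.0
    cell_height_um: float = 8.0
    jitter_um: float = 0.5
    convergence_rate_per_s: float = 1.5e-4  # ML compression / AP extension strain rate
    eps_t2_um: float = EPS_T2_UM

    # planted polarity
    enrichment_V: float = 2.0
    enrichment_T: float = 1.0
    myosin_enrichment_V: float = 1.8
    myosin_enrichment_T: float = 1.0

    # intensity model: dI/dt = kappa * (-dL/dt), i.e. the PCP intensity gains
    # kappa units per um of cumulative junction shrinkage
    intensity_length_coupling: float = 0.2
    cytoplasm_baseline: float = 1.0
    membrane_baseline: float = 1.0
    membrane_cytoplasm_level: float = 0.1
    membrane_density_coeff: float = 0.15
    noise_sd: float = 0.1

    # myosin / PCP pulses
    pulse_rate_per_min: float = 1.0
    pulse_amplitude: float = 0.35
    pulse_duration_s: float = 60.0
    pulse_coupling_rho: float = 0.7
    pulse_lag_frames: int = 0

    # intercalation events
    t1_rate_per_cell_per_hr: float = 0.25
    n_t1_events: int | None = None  # explicit override of the rate-derived count
    shrink_bias: float = 0.9  # fraction of scheduled shrinking junctions that are V-class
    n_rosettes: int = 2
    t1_contraction_frames: int = 10
    rosette_hold_frames: int = 3

    # cell-shape reorientation regime for the epoch generator
    reorientation: str = "ml"  # "ml" (control) or "none" (PCP-disrupted)

    # FRAP
    frap_mobile_fraction: float = 0.6
    frap_tau_s: float = 25.0
    frap_dt_s: float = 5.0
    frap_n_prebleach: int = 5
    frap_total_s: float = 300.0
    frap_bleach_floor: float = 0.2
    frap_photofade_per_s: float = 2e-4
    frap_noise_sd: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 9:
            raise ConfigurationError("n_cells must be >= 9")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        for name in (
            "dt_s", "pulse_rate_per_min", "pulse_duration_s", "t1_rate_per_cell_per_hr",
            "frap_tau_s", "frap_dt_s", "frap_total_s",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.frap_mobile_fraction <= 1.0:
            raise ConfigurationError("frap_mobile_fraction must lie in [0, 1]")
        if abs(self.pulse_coupling_rho) > 1.0:
            raise ConfigurationError("|pulse_coupling_rho| must be <= 1")
        if not 0.0 <= self.shrink_bias <= 1.0:
            raise ConfigurationError("shrink_bias must lie in [0, 1]")
        if self.reorientation not in ("ml", "none"):
            raise ConfigurationError("reorientation must be 'ml' or 'none'")

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.dt_s

    @property
    def duration_hr(self) -> float:
        return self.duration_s / 3600.0


@dataclass
class SyntheticGroundTruth:
    """Book-keeping of everything the generator planted."""

    n_cells: int
    n_frames: int
    dt_s: float
    junction_class: dict[str, str] = field(default_factory=dict)
    junction_enrichment: dict[str, float] = field(default_factory=dict)
    myosin_enrichment: dict[str, float] = field(default_factory=dict)
    shrink_velocity_um_per_s: dict[str, float] = field(default_factory=dict)
    t1_events: list[dict] = field(default_factory=list)
    rosette_events: list[dict] = field(default_factory=list)
    coupling: dict = field(default_factory=dict)
    frap: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# mutable mesh used while simulating
# ---------------------------------------------------------------------------

class _Mesh:
    def __init__(self) -> None:
        self.vertices: dict[int, np.ndarray] = {}
        self.cells: dict[int, list[int]] = {}
        self._next_vid = 0

    def new_vertex(self, pos: np.ndarray) -> int:
        vid = self._next_vid
        self._next_vid = vid + 1
        self.vertices[vid] = np.asarray(pos, dtype=float).copy()
        return vid

    def snapshot_identity(self, frame_index: int, time_s: float) -> TissueFrame:
        """Snapshot whose vertex indices ARE the mesh vertex ids (valid only
        while ids are contiguous, i.e. before any topology change); used for
        event scheduling."""
        verts = np.zeros((self._next_vid, 2))
        for vid, p in self.vertices.items():
            verts[vid] = p
        cell_vertices = {cid: list(loop) for cid, loop in self.cells.items()}
        return TissueFrame.from_mesh(frame_index, time_s, verts, cell_vertices)

    def snapshot(self, frame_index: int, time_s: float) -> TissueFrame:
        used = sorted({v for loop in self.cells.values() for v in loop})
        index = {vid: i for i, vid in enumerate(used)}
        verts = np.array([self.vertices[v] for v in used])
        cell_vertices = {cid: [index[v] for v in loop] for cid, loop in self.cells.items()}
        return TissueFrame.from_mesh(frame_index, time_s, verts, cell_vertices)

    def replace_vertex_single(self, cid: int, old: int, new: int) -> None:
        loop = self.cells[cid]
        self.cells[cid] = _dedupe([new if v == old else v for v in loop])

    def replace_vertex_pair(self, cid: int, old: int, pair: tuple[int, int]) -> None:
        """Replace ``old`` by two new vertices, picking the order that keeps
        the polygon simple (the wrong order produces a bow-tie)."""
        loop = self.cells[cid]
        i = loop.index(old)
        for order in (list(pair), list(pair)[::-1]):
            cand = loop[:i] + order + loop[i + 1:]
            poly = np.array([self.vertices[v] for v in cand])
            shp = _ShPoly(poly)
            if shp.is_valid and shp.area > 0:
                self.cells[cid] = cand
                return
        raise DataValidationError(f"cell {cid}: no valid vertex-split ordering found")


def _dedupe(loop: list[int]) -> list[int]:
    out = [v for i, v in enumerate(loop) if v != loop[i - 1]]
    return out


# ---------------------------------------------------------------------------
# event records
# ---------------------------------------------------------------------------

@dataclass
class _T1Event:
    pair: tuple[int, int]
    lateral_pair: tuple[int, int]
    v1: int
    v2: int
    start_frame: int
    swap_frame: int
    axis: str  # 'V' events resolve along AP, 'T' events along ML
    length_at_start: float = 0.0
    new_vids: tuple[int, int] | None = None
    grow_rate_um_per_s: float = 0.0


@dataclass
class _RosetteEvent:
    center: int  # cell whose two co-linear junctions contract
    pairs: tuple[tuple[int, int], tuple[int, int]]
    cells: tuple[int, ...]  # the >=5 rosette cells
    lateral_pair: tuple[int, int]
    v_left: int
    v_mid: int
    v_right: int
    start_frame: int
    collapse_frame: int
    resolve_frame: int
    formation_orientations: list[float] = field(default_factory=list)
    resolution_orientation: float | None = None
    lengths_at_start: tuple[float, float] = (0.0, 0.0)
    new_vids: tuple[int, int] | None = None
    grow_rate_um_per_s: float = 0.0


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

def _grid_shape(n_cells: int) -> tuple[int, int]:
    ncol = int(math.ceil(math.sqrt(n_cells)))
    nrow = int(math.ceil(n_cells / ncol))
    return nrow, ncol


def _build_lattice(
    n_cells: int, w: float, h: float, jitter: float, rng: np.random.Generator
) -> _Mesh:
    """Jittered brick-wall tessellation: every interior vertex has valence 3."""
    nrow, ncol = _grid_shape(n_cells)
    mesh = _Mesh()
    ncols_v = 2 * ncol + 2  # vertex columns per horizontal line, spacing w/2
    vid_of: dict[tuple[int, int], int] = {}
    for r in range(nrow + 1):
        for i in range(ncols_v):
            pos = np.array([i * w / 2.0, r * h])
            pos = pos + rng.uniform(-jitter, jitter, size=2)
            vid_of[(r, i)] = mesh.new_vertex(pos)
    for r in range(nrow):
        off = r % 2
        for c in range(ncol):
            i0 = 2 * c + off
            cid = r * ncol + c
            loop = [
                vid_of[(r, i0)], vid_of[(r, i0 + 1)], vid_of[(r, i0 + 2)],
                vid_of[(r + 1, i0 + 2)], vid_of[(r + 1, i0 + 1)], vid_of[(r + 1, i0)],
            ]
            mesh.cells[cid] = loop
    return mesh


# ---------------------------------------------------------------------------
# event scheduling
# ---------------------------------------------------------------------------

def _event_candidates(frame0: TissueFrame) -> list[dict]:
    """Single-edge interior junctions whose endpoints are valence-3 vertices,
    annotated with the lateral (quartet) cells."""
    incident = frame0.vertex_incident_cells()
    out = []
    for j in frame0.junctions:
        if j.is_boundary or len(j.vertex_ids) != 2:
            continue
        v1, v2 = j.vertex_ids
        c1 = incident.get(v1, set())
        c2 = incident.get(v2, set())
        if len(c1) != 3 or len(c2) != 3:
            continue
        a, b = j.cell_a, j.cell_b
        lat1 = (c1 - {a, b})
        lat2 = (c2 - {a, b})
        if len(lat1) != 1 or len(lat2) != 1:
            continue
        l1, l2 = lat1.pop(), lat2.pop()
        if len({a, b, l1, l2}) != 4:
            continue
        out.append(
            {"pair": (min(a, b), max(a, b)), "lateral": (min(l1, l2), max(l1, l2)),
             "v1": v1, "v2": v2, "class": j.class_label}
        )
    return out


def _rosette_candidates(frame0: TissueFrame) -> list[dict]:
    """Pairs of co-linear V-junctions of one cell sharing a valence-3 vertex."""
    incident = frame0.vertex_incident_cells()
    by_cell: dict[int, list] = {}
    for j in frame0.junctions:
        if j.is_boundary or len(j.vertex_ids) != 2 or j.class_label != "V":
            continue
        by_cell.setdefault(j.cell_a, []).append(j)
        by_cell.setdefault(j.cell_b, []).append(j)
    out = []
    for cid, juncs in sorted(by_cell.items()):
        for i in range(len(juncs)):
            for k in range(i + 1, len(juncs)):
                ja, jb = juncs[i], juncs[k]
                shared = set(ja.vertex_ids) & set(jb.vertex_ids)
                if len(shared) != 1:
                    continue
                v_mid = shared.pop()
                v_left = next(v for v in ja.vertex_ids if v != v_mid)
                v_right = next(v for v in jb.vertex_ids if v != v_mid)
                if any(len(incident.get(v, set())) != 3 for v in (v_left, v_mid, v_right)):
                    continue
                others_a = {ja.cell_a, ja.cell_b} - {cid}
                others_b = {jb.cell_a, jb.cell_b} - {cid}
                b1, b2 = others_a.pop(), others_b.pop()
                lat_l = incident[v_left] - {ja.cell_a, ja.cell_b}
                lat_r = incident[v_right] - {jb.cell_a, jb.cell_b}
                if len(lat_l) != 1 or len(lat_r) != 1:
                    continue
                c_l, c_r = lat_l.pop(), lat_r.pop()
                cells = (cid, b1, b2, c_l, c_r)
                if len(set(cells)) != 5:
                    continue
                out.append(
                    {"center": cid, "pairs": (ja.junction_id, jb.junction_id),
                     "cells": cells, "lateral": (min(c_l, c_r), max(c_l, c_r)),
                     "v_left": v_left, "v_mid": v_mid, "v_right": v_right}
                )
    return out


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_tissue(config: SimConfig) -> tuple[list[TissueFrame], SyntheticGroundTruth]:
    """Simulate the polygonal sheet and return frames + planted ground truth."""
    rng = _rng(config.seed, _STREAM_GEOMETRY)
    mesh = _build_lattice(
        config.n_cells, config.cell_width_um, config.cell_height_um,
        config.jitter_um, rng,
    )
    nrow, ncol = _grid_shape(config.n_cells)
    n_cells = nrow * ncol
    frame0 = mesh.snapshot_identity(0, 0.0)
    frame0.validate()

    gt = SyntheticGroundTruth(n_cells=n_cells, n_frames=config.n_frames, dt_s=config.dt_s)
    for j in frame0.junctions:
        if j.is_boundary:
            continue
        key = junction_id_str(j.junction_id)
        gt.junction_class[key] = j.class_label
        gt.junction_enrichment[key] = (
            config.enrichment_V if j.class_label == "V" else config.enrichment_T
        )
        gt.myosin_enrichment[key] = (
            config.myosin_enrichment_V if j.class_label == "V" else config.myosin_enrichment_T
        )
    gt.coupling = {
        "kappa": config.intensity_length_coupling,
        "rho": config.pulse_coupling_rho,
        "lag_frames": config.pulse_lag_frames,
    }

    frames = [mesh.snapshot(0, 0.0)]
    t1_events, rosette_events = _schedule_events(config, frame0, rng)
    for ev in t1_events:
        gt.t1_events.append(
            {"pair": list(ev.pair), "new_pair": list(ev.lateral_pair),
             "start_frame": ev.start_frame, "swap_frame": ev.swap_frame,
             "class_label": ev.axis}
        )

    cen = np.mean(
        [mesh.vertices[v] for loop in mesh.cells.values() for v in loop], axis=0
    )
    gamma = config.convergence_rate_per_s
    sx = 1.0 - gamma * config.dt_s
    sy = 1.0 + gamma * config.dt_s
    for t in range(1, config.n_frames):
        if gamma != 0.0:
            for vid in mesh.vertices:
                p = mesh.vertices[vid]
                mesh.vertices[vid] = cen + np.array(
                    [sx * (p[0] - cen[0]), sy * (p[1] - cen[1])]
                )
        for ev in t1_events:
            _step_t1(mesh, ev, t, config)
        for ev in rosette_events:
            _step_rosette(mesh, ev, t, config, frames[-1])
        frame = mesh.snapshot(t, t * config.dt_s)
        frames.append(frame)
        for ev in t1_events:
            if t == ev.swap_frame and ev.lateral_pair not in frame.adjacency():
                raise DataValidationError(f"T1 swap failed to create junction {ev.lateral_pair}")

    for ev in rosette_events:
        gt.rosette_events.append(
            {"center": ev.center, "cells": list(ev.cells),
             "pairs": [list(p) for p in ev.pairs], "new_pair": list(ev.lateral_pair),
             "start_frame": ev.start_frame, "formation_frame": ev.collapse_frame,
             "resolution_frame": ev.resolve_frame,
             "formation_orientations_deg": ev.formation_orientations,
             "resolution_orientation_deg": ev.resolution_orientation}
        )

    # record planted per-junction shrink velocity (flow component, frame 0)
    for j in frame0.junctions:
        if j.is_boundary:
            continue
        ang = math.radians(j.angle_deg)
        v_flow = gamma * j.length_um * (math.cos(ang) ** 2) - gamma * j.length_um * (
            math.sin(ang) ** 2
        )
        gt.shrink_velocity_um_per_s[junction_id_str(j.junction_id)] = v_flow
    return frames, gt


def _schedule_events(
    config: SimConfig, frame0: TissueFrame, rng: np.random.Generator
) -> tuple[list[_T1Event], list[_RosetteEvent]]:
    if config.n_t1_events is not None:
        n_t1 = int(config.n_t1_events)
    else:
        n_t1 = int(round(config.t1_rate_per_cell_per_hr * len(frame0.cells) * config.duration_hr))
    n_ros = int(config.n_rosettes)
    if n_t1 == 0 and n_ros == 0:
        return [], []

    w_max = max(2, min(config.t1_contraction_frames, config.n_frames - 4))
    last_swap = config.n_frames - 2
    # a swap at frame k contracts over [max(1, k - w_max), k); k >= 3 leaves
    # at least two contraction frames even when the window is truncated
    first_swap = 3
    if last_swap < first_swap:
        raise ConfigurationError("movie too short to schedule intercalation events")

    # events must not share vertices (their kinematics move those) nor any
    # junction identity (contracted pairs and the new lateral pairs must all
    # stay distinct); sharing a quartet *cell* is harmless, the polygon-loop
    # edits touch different vertices
    used_vids: set[int] = set()
    used_pairs: set[tuple[int, int]] = set()
    t1_events: list[_T1Event] = []
    rosette_events: list[_RosetteEvent] = []

    # rosettes first: they consume five cells each
    ros_cands = _rosette_candidates(frame0)
    rng.shuffle(ros_cands)
    hold = max(1, config.rosette_hold_frames)
    for cand in ros_cands:
        if len(rosette_events) == n_ros:
            break
        pairs = {cand["pairs"][0], cand["pairs"][1], cand["lateral"]}
        vids = {cand["v_left"], cand["v_mid"], cand["v_right"]}
        if pairs & used_pairs or vids & used_vids:
            continue
        last_collapse = config.n_frames - 2 - hold
        if last_collapse < first_swap:
            raise ConfigurationError("movie too short for rosette hold/resolution")
        collapse = int(rng.integers(first_swap, last_collapse + 1))
        start = max(1, collapse - w_max)
        rosette_events.append(
            _RosetteEvent(
                center=cand["center"], pairs=cand["pairs"], cells=cand["cells"],
                lateral_pair=cand["lateral"], v_left=cand["v_left"],
                v_mid=cand["v_mid"], v_right=cand["v_right"],
                start_frame=start, collapse_frame=collapse,
                resolve_frame=collapse + hold,
            )
        )
        used_pairs |= pairs
        used_vids |= vids
    if len(rosette_events) < n_ros:
        raise ConfigurationError(
            f"could only place {len(rosette_events)} of {n_ros} rosettes in this tissue"
        )

    cands = _event_candidates(frame0)
    rng.shuffle(cands)
    n_v = int(round(config.shrink_bias * n_t1))
    want = {"V": n_v, "T": n_t1 - n_v}
    for cand in cands:
        if sum(want.values()) == 0:
            break
        cls = cand["class"]
        if want.get(cls, 0) == 0:
            continue
        pairs = {cand["pair"], cand["lateral"]}
        vids = {cand["v1"], cand["v2"]}
        if pairs & used_pairs or vids & used_vids:
            continue
        swap = int(rng.integers(first_swap, last_swap + 1))
        start = max(1, swap - w_max)
        t1_events.append(
            _T1Event(
                pair=cand["pair"], lateral_pair=cand["lateral"],
                v1=cand["v1"], v2=cand["v2"], start_frame=start, swap_frame=swap,
                axis=cls,
            )
        )
        used_pairs |= pairs
        used_vids |= vids
        want[cls] -= 1
    if sum(want.values()) > 0:
        raise ConfigurationError(
            f"infeasible event schedule: {sum(want.values())} of {n_t1} T1 events "
            "could not be placed (tissue too small or too many events)"
        )
    return t1_events, rosette_events


def _contracted_length(l_start: float, i: int, window: int, eps: float) -> float:
    return max(l_start * (1.0 - i / window), 0.5 * eps)


def _step_t1(mesh: _Mesh, ev: _T1Event, t: int, config: SimConfig) -> None:
    if t < ev.start_frame or (ev.new_vids is not None and t < ev.swap_frame):
        return
    window = ev.swap_frame - ev.start_frame
    if t < ev.swap_frame:
        p1, p2 = mesh.vertices[ev.v1], mesh.vertices[ev.v2]
        cur = float(np.linalg.norm(p1 - p2))
        if t == ev.start_frame:
            ev.length_at_start = cur
            ev.grow_rate_um_per_s = cur / (window * config.dt_s)
        target = _contracted_length(
            ev.length_at_start, t - ev.start_frame + 1, window, config.eps_t2_um
        )
        m = (p1 + p2) / 2.0
        scale = target / cur if cur > 0 else 0.0
        mesh.vertices[ev.v1] = m + scale * (p1 - m)
        mesh.vertices[ev.v2] = m + scale * (p2 - m)
        return
    direction = np.array([0.0, 1.0]) if ev.axis == "V" else np.array([1.0, 0.0])
    if t == ev.swap_frame:
        p1, p2 = mesh.vertices[ev.v1], mesh.vertices[ev.v2]
        m = (p1 + p2) / 2.0
        g0 = 2.0 * config.eps_t2_um
        va = mesh.new_vertex(m + (g0 / 2.0) * direction)
        vb = mesh.new_vertex(m - (g0 / 2.0) * direction)
        a, b = ev.pair
        for cid in (a, b):
            cen = np.mean([mesh.vertices[v] for v in mesh.cells[cid]], axis=0)
            side = va if float(np.dot(cen - m, direction)) >= 0 else vb
            loop = [side if v in (ev.v1, ev.v2) else v for v in mesh.cells[cid]]
            mesh.cells[cid] = _dedupe(loop)
        for cid, old in ((ev.lateral_pair[0], None), (ev.lateral_pair[1], None)):
            loop = mesh.cells[cid]
            old = ev.v1 if ev.v1 in loop else ev.v2
            mesh.replace_vertex_pair(cid, old, (va, vb))
        del mesh.vertices[ev.v1]
        del mesh.vertices[ev.v2]
        ev.new_vids = (va, vb)
        return
    # growth of the new junction
    va, vb = ev.new_vids
    pa, pb = mesh.vertices[va], mesh.vertices[vb]
    m = (pa + pb) / 2.0
    g0 = 2.0 * config.eps_t2_um
    cap = 0.45 * (config.cell_height_um if ev.axis == "V" else config.cell_width_um)
    g = min(g0 + ev.grow_rate_um_per_s * config.dt_s * (t - ev.swap_frame), cap)
    mesh.vertices[va] = m + (g / 2.0) * direction
    mesh.vertices[vb] = m - (g / 2.0) * direction


def _step_rosette(
    mesh: _Mesh, ev: _RosetteEvent, t: int, config: SimConfig, prev_frame: TissueFrame
) -> None:
    if t < ev.start_frame:
        return
    window = ev.collapse_frame - ev.start_frame
    if t < ev.collapse_frame:
        pm = mesh.vertices[ev.v_mid]
        for k, vid in enumerate((ev.v_left, ev.v_right)):
            p = mesh.vertices[vid]
            cur = float(np.linalg.norm(p - pm))
            if t == ev.start_frame:
                ls = list(ev.lengths_at_start)
                ls[k] = cur
                ev.lengths_at_start = tuple(ls)
                ev.grow_rate_um_per_s = max(ev.grow_rate_um_per_s, cur / (window * config.dt_s))
            target = _contracted_length(
                ev.lengths_at_start[k], t - ev.start_frame + 1, window, config.eps_t2_um
            )
            scale = target / cur if cur > 0 else 0.0
            mesh.vertices[vid] = pm + scale * (p - pm)
        return
    if t == ev.collapse_frame:
        # record formation orientations from the last pre-collapse frame
        jm = prev_frame.junction_map()
        for pair in ev.pairs:
            if pair in jm:
                ev.formation_orientations.append(jm[pair].angle_deg)
        for cid in ev.cells:
            loop = [ev.v_mid if v in (ev.v_left, ev.v_right) else v for v in mesh.cells[cid]]
            mesh.cells[cid] = _dedupe(loop)
        del mesh.vertices[ev.v_left]
        del mesh.vertices[ev.v_right]
        return
    if t < ev.resolve_frame:
        return  # rosette holds: >=5 cells share v_mid
    direction = np.array([0.0, 1.0])  # rosettes resolve along AP
    if t == ev.resolve_frame:
        pm = mesh.vertices[ev.v_mid]
        g0 = 2.0 * config.eps_t2_um
        va = mesh.new_vertex(pm + (g0 / 2.0) * direction)
        vb = mesh.new_vertex(pm - (g0 / 2.0) * direction)
        lat = set(ev.lateral_pair)
        for cid in ev.cells:
            if cid in lat:
                mesh.replace_vertex_pair(cid, ev.v_mid, (va, vb))
            else:
                cen = np.mean([mesh.vertices[v] for v in mesh.cells[cid]], axis=0)
                side = va if float(np.dot(cen - pm, direction)) >= 0 else vb
                mesh.replace_vertex_single(cid, ev.v_mid, side)
        del mesh.vertices[ev.v_mid]
        ev.new_vids = (va, vb)
        ev.resolution_orientation = 90.0
        return
    va, vb = ev.new_vids
    pa, pb = mesh.vertices[va], mesh.vertices[vb]
    m = (pa + pb) / 2.0
    g0 = 2.0 * config.eps_t2_um
    cap = 0.45 * config.cell_height_um
    rate = ev.grow_rate_um_per_s if ev.grow_rate_um_per_s > 0 else g0 / config.dt_s
    g = min(g0 + rate * config.dt_s * (t - ev.resolve_frame), cap)
    mesh.vertices[va] = m + (g / 2.0) * direction
    mesh.vertices[vb] = m - (g / 2.0) * direction


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

class _PulseTrain:
    """Raised-cosine bumps arriving by a Poisson process, mean-centred.

    Mean-centring keeps the planted enrichment baselines unbiased; it does
    not alter the delta-series, so the planted coupling rho is unaffected.
    """

    def __init__(
        self, rate_per_s: float, amplitude: float, duration_s: float,
        t_min: float, t_max: float, rng: np.random.Generator,
    ) -> None:
        span = (t_max - t_min) + 2 * duration_s
        n = rng.poisson(rate_per_s * span) if rate_per_s > 0 else 0
        self.arrivals = t_min - duration_s + span * rng.random(n)
        self.amplitude = amplitude
        self.duration = duration_s
        self.mean = rate_per_s * amplitude * duration_s / 2.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for ti in self.arrivals:
            u = (t - ti) / self.duration
            mask = (u >= 0) & (u <= 1)
            if np.any(mask):
                out[mask] += self.amplitude * 0.5 * (1 - np.cos(2 * np.pi * u[mask]))
        return out - self.mean


def generate_intensities(
    frames: Sequence[TissueFrame],
    ground_truth: SyntheticGroundTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-junction traces (membrane/pcp/myosin) and per-cell cytoplasm traces.

    PCP channel = class baseline + kappa * cumulative shrinkage + pulse mix
    (the intensity *rate of change* is kappa times the shrink velocity);
    myosin channel = class baseline + pulse mix (shared component lagged by
    the planted lag); membrane channel = baseline + mild density term.
    The PCP/myosin pulse mix uses weights sqrt(rho) / sqrt(1 - rho) on a
    shared and an independent train, which plants a zero-lag delta-series
    correlation of exactly rho in expectation.
    """
    rng = _rng(config.seed, _STREAM_INTENSITY)
    dt = config.dt_s
    lag_s = config.pulse_lag_frames * dt
    rho = float(config.pulse_coupling_rho)
    w_shared = math.sqrt(abs(rho))
    w_indep = math.sqrt(1.0 - abs(rho))
    sign = 1.0 if rho >= 0 else -1.0
    rate_s = config.pulse_rate_per_min / 60.0
    t_all = np.array([f.time_s for f in frames])
    t_min, t_max = float(t_all[0]) - abs(lag_s), float(t_all[-1]) + abs(lag_s)

    presence: dict[tuple[int, int], list[tuple[int, float, float, float]]] = {}
    for f in frames:
        for j in f.junctions:
            if j.is_boundary:
                continue
            presence.setdefault(j.junction_id, []).append(
                (f.frame_index, f.time_s, j.length_um, j.angle_deg)
            )

    n_clamped = 0
    rows = []
    for jid in sorted(presence):
        occ = presence[jid]
        fr = np.array([o[0] for o in occ])
        ts = np.array([o[1] for o in occ])
        ln = np.array([o[2] for o in occ])
        ang = np.array([o[3] for o in occ])
        cls = classify_junction(float(ang[0]))
        key = junction_id_str(jid)
        enr = ground_truth.junction_enrichment.get(
            key, config.enrichment_V if cls == "V" else config.enrichment_T
        )
        myo = ground_truth.myosin_enrichment.get(
            key, config.myosin_enrichment_V if cls == "V" else config.myosin_enrichment_T
        )
        if key not in ground_truth.junction_class:
            ground_truth.junction_class[key] = cls
            ground_truth.junction_enrichment[key] = enr
            ground_truth.myosin_enrichment[key] = myo

        # cumulative shrinkage (um, positive when contracted below first length)
        shrinkage = ln[0] - ln

        shared = _PulseTrain(rate_s, config.pulse_amplitude, config.pulse_duration_s,
                             t_min, t_max, rng)
        indep_p = _PulseTrain(rate_s, config.pulse_amplitude, config.pulse_duration_s,
                              t_min, t_max, rng)
        indep_m = _PulseTrain(rate_s, config.pulse_amplitude, config.pulse_duration_s,
                              t_min, t_max, rng)
        base = config.cytoplasm_baseline
        pcp = (
            base * enr
            + config.intensity_length_coupling * shrinkage
            + w_shared * shared(ts)
            + w_indep * indep_p(ts)
        )
        myosin = (
            base * myo
            + sign * w_shared * shared(ts - lag_s)
            + w_indep * indep_m(ts)
        )
        mem = config.membrane_baseline * (
            1.0 + config.membrane_density_coeff * (ln[0] / np.maximum(ln, 1e-9) - 1.0)
        )
        if config.noise_sd > 0:
            pcp = pcp + rng.normal(0.0, config.noise_sd, size=len(ts))
            myosin = myosin + rng.normal(0.0, config.noise_sd, size=len(ts))
            mem = mem + rng.normal(0.0, config.noise_sd, size=len(ts))
        floor = 1e-3
        for arr in (pcp, myosin, mem):
            bad = arr < floor
            n_clamped += int(bad.sum())
            arr[bad] = floor
        for ch, vals in (("membrane", mem), ("pcp", pcp), ("myosin", myosin)):
            for k in range(len(fr)):
                rows.append(
                    (key, int(fr[k]), float(ts[k]), float(ln[k]), float(ang[k]),
                     ch, float(vals[k]))
                )
    if n_clamped:
        logger.warning("clamped %d negative intensity samples to the floor", n_clamped)

    traces = pd.DataFrame(
        rows,
        columns=["junction_id", "frame", "time_s", "length_um", "angle_deg",
                 "channel", "mean_intensity"],
    )

    cyto_rows = []
    cyto_levels = {
        "membrane": config.membrane_cytoplasm_level * config.membrane_baseline,
        "pcp": config.cytoplasm_baseline,
        "myosin": config.cytoplasm_baseline,
    }
    cyto_noise = 0.3 * config.noise_sd
    for f in frames:
        for c in f.cells:
            for ch, level in cyto_levels.items():
                val = level + (rng.normal(0.0, cyto_noise) if cyto_noise > 0 else 0.0)
                cyto_rows.append(
                    (c.cell_id, f.frame_index, f.time_s, ch, max(val, 1e-3))
                )
    cytoplasm = pd.DataFrame(
        cyto_rows, columns=["cell_id", "frame", "time_s", "channel", "mean_intensity"]
    )
    return traces, cytoplasm


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def frap_recovery_model(
    t: np.ndarray, t_bleach: float, floor: float, mobile: float, tau_s: float
) -> np.ndarray:
    """Normalized recovery curve: 1 pre-bleach, then
    floor + mobile * (1 - floor) * (1 - exp(-(t - t_bleach)/tau))."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    post = t >= t_bleach
    dt = t[post] - t_bleach
    out[post] = floor + mobile * (1.0 - floor) * (1.0 - np.exp(-dt / tau_s))
    return out


def generate_frap(
    config: SimConfig,
    *,
    mobile_fraction: float | None = None,
    tau_s: float | None = None,
    delta_length_um: float = 0.0,
    record_id: str = "frap-0",
    rng: np.random.Generator | None = None,
) -> FrapRecord:
    """One synthetic bleach experiment with planted (M, tau).

    The bleached-region trace drops to ``frap_bleach_floor`` at the bleach
    frame and recovers exponentially; the unbleached reference carries the
    acquisition photofading that the double normalization must cancel.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_FRAP)
    mobile = config.frap_mobile_fraction if mobile_fraction is None else float(mobile_fraction)
    tau = config.frap_tau_s if tau_s is None else float(tau_s)
    if not 0.0 <= mobile <= 1.0:
        raise ConfigurationError("mobile fraction must lie in [0, 1]")
    if tau <= 0:
        raise ConfigurationError("tau_s must be positive")
    n_pre = int(config.frap_n_prebleach)
    n_post = int(round(config.frap_total_s / config.frap_dt_s)) + 1
    if n_post < 2:
        raise ConfigurationError("bleach at final frame: no recovery to fit")
    times = np.arange(n_pre + n_post) * config.frap_dt_s
    t_bleach = times[n_pre]

    g = frap_recovery_model(times, t_bleach, config.frap_bleach_floor, mobile, tau)
    fade = np.exp(-config.frap_photofade_per_s * times)
    f_raw, r_raw, bg = 1000.0, 1000.0, 50.0
    bleach = bg + f_raw * fade * g
    reference = bg + r_raw * fade
    if config.frap_noise_sd > 0:
        bleach = bleach + rng.normal(0, config.frap_noise_sd * f_raw, size=len(times))
        reference = reference + rng.normal(0, config.frap_noise_sd * r_raw, size=len(times))
    background = np.full_like(times, bg)
    length = 5.0 + delta_length_um * (times / times[-1])
    return FrapRecord(
        record_id=record_id,
        junction_id=record_id,
        times_s=times,
        t_bleach_s=float(t_bleach),
        bleach_trace=bleach,
        reference_trace=reference,
        background_trace=background,
        length_series_um=length,
        planted_mobile_fraction=mobile,
        planted_tau_s=tau,
    )


def generate_frap_cohort(
    config: SimConfig, n_records: int = 30
) -> tuple[list[FrapRecord], list[dict]]:
    """A cohort of bleach experiments with a planted negative relation
    between junction-length change and nonmobile fraction (faster-shrinking
    junctions carry a higher stable fraction)."""
    rng = _rng(config.seed, _STREAM_FRAP)
    records, truth = [], []
    base_nonmobile = 1.0 - config.frap_mobile_fraction
    for i in range(n_records):
        if i % 2 == 0:
            dl = float(rng.uniform(-2.2, -0.5))  # shrinking
        else:
            dl = float(rng.uniform(-0.4, 0.4))  # nonshrinking
        nonmobile = float(
            np.clip(base_nonmobile - 0.22 * dl + rng.normal(0, 0.04), 0.05, 0.9)
        )
        tau = float(config.frap_tau_s * math.exp(rng.normal(0.0, 0.2)))
        rec = generate_frap(
            config, mobile_fraction=1.0 - nonmobile, tau_s=tau,
            delta_length_um=dl, record_id=f"frap-{i}", rng=rng,
        )
        records.append(rec)
        truth.append(
            {"record_id": rec.record_id, "mobile_fraction": 1.0 - nonmobile,
             "tau_s": tau, "delta_length_um": dl}
        )
    return records, truth


# ---------------------------------------------------------------------------
# cell-reorientation epochs
# ---------------------------------------------------------------------------

def generate_reorientation_epochs(config: SimConfig) -> tuple[TissueFrame, TissueFrame]:
    """Early/late tissue snapshots with planted cell long-axis behavior.

    Early epoch: cells elongated along AP (long axis near 90 deg).  Late
    epoch: for the control regime ("ml") cells have reoriented toward the
    mediolateral axis; for disrupted regimes ("none") they remain AP-aligned.
    Intercalation, not deformation, drives this in vivo, so the epochs are
    generated as independent snapshots of the same cell field rather than as
    endpoints of the kinematic flow.
    """
    rng = _rng(config.seed, _STREAM_EPOCHS)
    w, h = config.cell_width_um, config.cell_height_um
    scale = 1.35
    early = _build_lattice(config.n_cells, w / scale, h * scale, config.jitter_um, rng)
    if config.reorientation == "ml":
        late = _build_lattice(config.n_cells, w * scale, h / scale, config.jitter_um, rng)
    else:
        late = _build_lattice(config.n_cells, w / scale, h * scale, config.jitter_um, rng)
    f_early = early.snapshot(0, 0.0)
    f_late = late.snapshot(1, config.duration_s)
    return f_early, f_late


def preset_like(config: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
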