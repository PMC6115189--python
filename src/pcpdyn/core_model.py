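"""Geometric and temporal data model for segmented epithelial time-lapses.

Conventions (used throughout the package):

* mediolateral (ML) axis = +x, anteroposterior (AP) axis = y with anterior
  at -y (top of the image); coordinates in micrometres.
* frame indices are 0-based; time is in seconds.
* junction and cell-axis orientations are axial angles folded into
  [0, 90] degrees relative to the ML axis.
* a junction within 45 degrees of the ML axis is a "V-junction"
  (it separates AP-neighbor cells and preferentially shrinks during
  convergent extension); the rest are "T-junctions".  The continuous
  boundary is V = [0, 45], T = (45, 90].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circular import axial_mean_deg
from .errors import DataValidationError, DegenerateGeometryError

__all__ = [
    "V_T_BOUNDARY_DEG",
    "EPS_T2_UM",
    "Cell",
    "Junction",
    "TissueFrame",
    "JunctionTrack",
    "segment_angle",
    "classify_junction",
    "cell_long_axis",
    "polygon_area",
    "polygon_centroid",
    "build_tracks",
    "save_mesh",
    "load_mesh",
    "save_traces",
    "load_traces",
    "TRACE_COLUMNS",
]

#: V/T class boundary in degrees off the mediolateral axis.
V_T_BOUNDARY_DEG = 45.0

#: Default length (um) below which a junction is considered fully
#: contracted (T2 configuration); sub-resolution for confocal data.
EPS_T2_UM = 0.3

MESH_SCHEMA_VERSION = 1

TRACE_COLUMNS = [
    "junction_id",
    "frame",
    "time_s",
    "length_um",
    "angle_deg",
    "channel",
    "mean_intensity",
]


# ---------------------------------------------------------------------------
# scalar geometry
# ---------------------------------------------------------------------------

def segment_angle(p_start: Sequence[float], p_end: Sequence[float]) -> float:
    """Acute angle (degrees, in [0, 90]) between a chord and the ML (x) axis.

    Axial convention: invariant under endpoint swap and under reflection
    about either axis.

    Raises
    ------
    DegenerateGeometryError
        If the endpoints coincide.
    """
    dx = float(p_end[0]) - float(p_start[0])
    dy = float(p_end[1]) - float(p_start[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("segment endpoints coincide; angle undefined")
    ang = math.degrees(math.atan2(abs(dy), abs(dx)))
    # atan2(|dy|, |dx|) already lies in [0, 90]
    return ang


def classify_junction(angle_deg: float) -> str:
    """Classify a junction orientation as 'V' (<= 45 deg off ML) or 'T'.

    Raises
    ------
    DataValidationError
        If the angle is outside [0, 90].
    """
    if not (0.0 <= angle_deg <= 90.0):
        raise DataValidationError(
            f"junction angle {angle_deg!r} outside the axial range [0, 90]"
        )
    return "V" if angle_deg <= V_T_BOUNDARY_DEG else "T"


def polygon_area(poly: np.ndarray) -> float:
    """Signed area of a polygon given as an (n, 2) vertex array (shoelace)."""
    x = poly[:, 0]
    y = poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    x = poly[:, 0]
    y = poly[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise DegenerateGeometryError("zero-area polygon has no centroid")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _polygon_covariance(poly: np.ndarray) -> np.ndarray:
    """Covariance matrix of the uniform density over a simple polygon.

    Closed-form second central area moments via Green's theorem; the sign
    of the shoelace area cancels, so vertex orientation does not matter.
    """
    x = poly[:, 0]
    y = poly[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise DegenerateGeometryError("zero-area polygon has no covariance")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    sxx = np.sum((x * x + x * xn + xn * xn) * cross) / (12.0 * a)
    syy = np.sum((y * y + y * yn + yn * yn) * cross) / (12.0 * a)
    sxy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / (24.0 * a)
    return np.array([[sxx - cx * cx, sxy - cx * cy], [sxy - cx * cy, syy - cy * cy]])


def cell_long_axis(
    polygon: np.ndarray, *, isotropy_tol: float = 1e-9
) -> tuple[float, float]:
    """Principal-axis orientation and elongation of a cell outline.

    Computed from the second central moments of the polygon (uniform
    density).  Returns ``(long_axis_angle_deg, aspect_ratio)`` with the
    orientation folded into [0, 90] off the ML axis and
    ``aspect_ratio = sqrt(lambda_major / lambda_minor)`` of the covariance
    eigenvalues.  For an isotropic shape (eigenvalues equal within
    tolerance) the orientation is undefined and returned as NaN with
    aspect ratio 1.0.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise DegenerateGeometryError("polygon must be an (n>=3, 2) array")
    if abs(polygon_area(poly)) <= 0.0:
        raise DegenerateGeometryError("zero-area polygon has no long axis")
    cov = _polygon_covariance(poly)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_minor <= 0.0:
        raise DegenerateGeometryError("degenerate (collinear) polygon")
    if (lam_major - lam_minor) <= isotropy_tol * (lam_major + lam_minor):
        return float("nan"), 1.0
    vx, vy = evecs[:, 1]
    angle = math.degrees(math.atan2(abs(float(vy)), abs(float(vx))))
    return angle, math.sqrt(lam_major / lam_minor)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cell:
    """One cell at one time point: polygon, centroid and shape descriptors."""

    cell_id: int
    vertex_ids: tuple[int, ...]
    polygon: np.ndarray  # (k, 2) um
    centroid: np.ndarray
    long_axis_angle_deg: float  # NaN when isotropic
    aspect_ratio: float

    @classmethod
    def from_polygon(cls, cell_id: int, vertex_ids: Sequence[int], polygon: np.ndarray) -> "Cell":
        poly = np.asarray(polygon, dtype=float)
        angle, aspect = cell_long_axis(poly)
        return cls(
            cell_id=int(cell_id),
            vertex_ids=tuple(int(v) for v in vertex_ids),
            polygon=poly,
            centroid=polygon_centroid(poly),
            long_axis_angle_deg=angle,
            aspect_ratio=aspect,
        )


@dataclass(frozen=True)
class Junction:
    """A shared cell-cell interface at one time point.

    ``cell_b`` is ``None`` for tissue-boundary junctions, which are flagged
    and excluded from population statistics.
    """

    cell_a: int
    cell_b: int | None
    vertex_ids: tuple[int, ...]
    polyline: np.ndarray  # (m, 2) um, ordered
    length_um: float
    angle_deg: float
    class_label: str  # 'V' or 'T'

    @property
    def junction_id(self) -> tuple[int, int]:
        """Unordered cell-ID pair (boundary junctions use -1 for the void side)."""
        b = -1 if self.cell_b is None else self.cell_b
        return (min(self.cell_a, b), max(self.cell_a, b))

    @property
    def is_boundary(self) -> bool:
        return self.cell_b is None


def junction_id_str(jid: tuple[int, int]) -> str:
    return f"{jid[0]}-{jid[1]}"


def parse_junction_id(s: str) -> tuple[int, int]:
    # boundary ids are (-1, c) -> "-1-c"
    parts = s.split("-")
    if parts[0] == "":
        a, b = -int(parts[1]), int(parts[2])
    else:
        a, b = int(parts[0]), int(parts[1])
    return (min(a, b), max(a, b))


@dataclass
class TissueFrame:
    """Segmented polygonal geometry of the epithelium at one time point."""

    frame_index: int
    time_s: float
    vertices: np.ndarray  # (n, 2) um
    cells: list[Cell]
    junctions: list[Junction]

    # -- derived lookups -----------------------------------------------------
    def junction_map(self) -> dict[tuple[int, int], Junction]:
        return {j.junction_id: j for j in self.junctions}

    def adjacency(self) -> set[tuple[int, int]]:
        """Unordered interior cell-pair adjacencies."""
        return {j.junction_id for j in self.junctions if not j.is_boundary}

    def cell_map(self) -> dict[int, Cell]:
        return {c.cell_id: c for c in self.cells}

    def vertex_incident_cells(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for c in self.cells:
            for vid in c.vertex_ids:
                out.setdefault(vid, set()).add(c.cell_id)
        return out

    # -- construction --------------------------------------------------------
    @classmethod
    def from_mesh(
        cls,
        frame_index: int,
        time_s: float,
        vertices: np.ndarray,
        cell_vertices: Mapping[int, Sequence[int]],
    ) -> "TissueFrame":
        """Build a frame from shared vertices and per-cell vertex-index loops.

        Junctions are derived by grouping polygon edges shared between cell
        pairs into maximal polylines.
        """
        verts = np.asarray(vertices, dtype=float)
        cells = []
        for cid in sorted(cell_vertices):
            vids = list(cell_vertices[cid])
            if len(set(vids)) != len(vids) or len(vids) < 3:
                raise DataValidationError(f"cell {cid}: invalid vertex loop {vids}")
            cells.append(Cell.from_polygon(cid, vids, verts[vids]))
        junctions = _derive_junctions(verts, cells)
        return cls(frame_index=int(frame_index), time_s=float(time_s),
                   vertices=verts, cells=cells, junctions=junctions)

    def validate(self) -> None:
        """Check topological invariants; raise DataValidationError on failure.

        Cells must be simple with positive area, every interior junction must
        reference two distinct cells, and the planar-complex Euler relation
        V - E + (C + 1) = 2 must hold (counting the outer face).
        """
        from shapely.geometry import Polygon as _ShPoly

        for c in self.cells:
            p = _ShPoly(c.polygon)
            if not p.is_valid or p.area <= 0:
                raise DataValidationError(f"cell {c.cell_id}: non-simple or zero-area polygon")
        seen: set[tuple[int, int]] = set()
        for j in self.junctions:
            if not j.is_boundary and j.cell_a == j.cell_b:
                raise DataValidationError("junction references a single cell twice")
            if j.junction_id in seen:
                raise DataValidationError(f"duplicate junction id {j.junction_id}")
            seen.add(j.junction_id)
        edges: set[tuple[int, int]] = set()
        used_vids: set[int] = set()
        for c in self.cells:
            vids = c.vertex_ids
            used_vids.update(vids)
            for a, b in zip(vids, vids[1:] + vids[:1]):
                edges.add((min(a, b), max(a, b)))
        v = len(used_vids)
        e = len(edges)
        f = len(self.cells) + 1
        if v - e + f != 2:
            raise DataValidationError(f"Euler relation violated: V={v} E={e} F={f}")


def _derive_junctions(vertices: np.ndarray, cells: list[Cell]) -> list[Junction]:
    # edge (unordered vertex pair) -> cells using it
    edge_cells: dict[tuple[int, int], list[int]] = {}
    for c in cells:
        vids = c.vertex_ids
        for a, b in zip(vids, vids[1:] + vids[:1]):
            key = (min(a, b), max(a, b))
            edge_cells.setdefault(key, []).append(c.cell_id)
    pair_edges: dict[tuple[int, int | None], list[tuple[int, int]]] = {}
    for edge, cids in edge_cells.items():
        if len(cids) > 2:
            raise DataValidationError(f"edge {edge} shared by >2 cells: {cids}")
        if len(cids) == 2:
            key = (min(cids), max(cids))
        else:
            key = (cids[0], None)
        pair_edges.setdefault(key, []).append(edge)

    junctions: list[Junction] = []
    for (ca, cb), edges in sorted(
        pair_edges.items(), key=lambda kv: (kv[0][0], -1 if kv[0][1] is None else kv[0][1])
    ):
        for vid_path in _chain_edges(edges):
            poly = vertices[list(vid_path)]
            seglens = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            length = float(seglens.sum())
            ang = segment_angle(poly[0], poly[-1])
            junctions.append(
                Junction(
                    cell_a=ca,
                    cell_b=cb,
                    vertex_ids=tuple(vid_path),
                    polyline=poly,
                    length_um=length,
                    angle_deg=ang,
                    class_label=classify_junction(ang),
                )
            )
    # a cell pair sharing two disjoint interfaces would emit a duplicate id
    ids = [j.junction_id for j in junctions if not j.is_boundary]
    if len(ids) != len(set(ids)):
        raise DataValidationError("a cell pair shares more than one disjoint interface")
    return junctions


def _chain_edges(edges: list[tuple[int, int]]) -> list[list[int]]:
    """Order a set of undirected edges into maximal simple paths."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    remaining = {tuple(sorted(e)) for e in edges}
    endpoints = sorted(v for v, nbrs in adj.items() if len(nbrs) == 1)
    paths: list[list[int]] = []
    starts = endpoints if endpoints else sorted(adj)
    for start in starts:
        if not any(start in e for e in remaining):
            continue
        path = [start]
        cur = start
        while True:
            nxt = None
            for nb in sorted(adj[cur]):
                if (min(cur, nb), max(cur, nb)) in remaining:
                    nxt = nb
                    break
            if nxt is None:
                break
            remaining.discard((min(cur, nxt), max(cur, nxt)))
            path.append(nxt)
            cur = nxt
        if len(path) > 1:
            paths.append(path)
        if not remaining:
            break
    if remaining:
        raise DataValidationError("could not chain junction edges into simple paths")
    return paths


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class JunctionTrack:
    """One junction identity followed across a contiguous frame range.

    ``fate`` is ``resolved_T2`` when the track ends (before the movie does)
    with a final length below the T2 threshold, ``newly_formed`` when it
    starts after the first frame, else ``persists``.  A pair that loses and
    later regains contact yields two distinct tracks (the regained contact
    is a *new* junction in T2->T3 semantics).
    """

    junction_id: tuple[int, int]
    frames: np.ndarray  # contiguous frame indices
    times_s: np.ndarray
    length_series: np.ndarray
    angle_series: np.ndarray
    intensity_series: dict[str, np.ndarray] = field(default_factory=dict)
    fate: str = "persists"

    def __post_init__(self) -> None:
        n = len(self.frames)
        for name in ("times_s", "length_series", "angle_series"):
            if len(getattr(self, name)) != n:
                raise DataValidationError(f"track {self.junction_id}: {name} length mismatch")
        for ch, arr in self.intensity_series.items():
            if len(arr) != n:
                raise DataValidationError(
                    f"track {self.junction_id}: channel {ch} length mismatch"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def mean_angle_deg(self) -> float:
        """Axial mean orientation over the track."""
        return axial_mean_deg(self.angle_series)

    @property
    def orientation_drift_deg(self) -> float:
        """Max - min of the angle series (orientation stability measure)."""
        return float(np.max(self.angle_series) - np.min(self.angle_series))

    @property
    def delta_length_um(self) -> float:
        return float(self.length_series[-1] - self.length_series[0])


def build_tracks(
    frames: Sequence[TissueFrame],
    traces: pd.DataFrame | None = None,
    *,
    eps_t2_um: float = EPS_T2_UM,
    include_boundary: bool = False,
) -> list[JunctionTrack]:
    """Assemble per-junction tracks from a frame sequence.

    One track is emitted per maximal contiguous run of frames over which a
    cell pair shares a junction.  If ``traces`` (the standard long-format
    trace table) is given, per-channel intensities are attached.
    """
    if len(frames) == 0:
        raise DataValidationError("no frames given")
    times = np.array([f.time_s for f in frames], dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise DataValidationError("frame times must be strictly increasing")
    idx = np.array([f.frame_index for f in frames])

    occurrences: dict[tuple[int, int], list[tuple[int, Junction]]] = {}
    for k, fr in enumerate(frames):
        seen: set[tuple[int, int]] = set()
        for j in fr.junctions:
            if j.is_boundary and not include_boundary:
                continue
            if j.junction_id in seen:
                raise DataValidationError(
                    f"duplicate junction id {j.junction_id} in frame {fr.frame_index}"
                )
            seen.add(j.junction_id)
            occurrences.setdefault(j.junction_id, []).append((k, j))

    trace_lookup: dict[tuple[str, int, str], float] = {}
    channels: list[str] = []
    if traces is not None:
        channels = sorted(traces["channel"].unique())
        trace_lookup = {
            (row.junction_id, int(row.frame), row.channel): float(row.mean_intensity)
            for row in traces.itertuples()
        }

    last_k = len(frames) - 1
    tracks: list[JunctionTrack] = []
    for jid in sorted(occurrences):
        occ = occurrences[jid]
        runs: list[list[tuple[int, Junction]]] = [[occ[0]]]
        for prev, cur in zip(occ, occ[1:]):
            if cur[0] == prev[0] + 1:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            ks = [k for k, _ in run]
            juncs = [j for _, j in run]
            lengths = np.array([j.length_um for j in juncs])
            angles = np.array([j.angle_deg for j in juncs])
            intensity: dict[str, np.ndarray] = {}
            for ch in channels:
                key_id = junction_id_str(jid)
                intensity[ch] = np.array(
                    [trace_lookup.get((key_id, int(idx[k]), ch), np.nan) for k in ks]
                )
            ends_early = ks[-1] < last_k
            starts_late = ks[0] > 0
            if ends_early and lengths[-1] < eps_t2_um:
                fate = "resolved_T2"
            elif starts_late:
                fate = "newly_formed"
            else:
                fate = "persists"
            tracks.append(
                JunctionTrack(
                    junction_id=jid,
                    frames=idx[ks],
                    times_s=times[ks],
                    length_series=lengths,
                    angle_series=angles,
                    intensity_series=intensity,
                    fate=fate,
                )
            )
    return tracks


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def save_mesh(frames: Iterable[TissueFrame], path: str | Path) -> None:
    """Write a mesh time series as the versioned JSON interchange document."""
    doc = {
        "schema_version": MESH_SCHEMA_VERSION,
        "units": {"length": "um", "time": "s"},
        "frames": [
            {
                "frame_index": f.frame_index,
                "time_s": f.time_s,
                "vertices": np.asarray(f.vertices).tolist(),
                "cells": [
                    {"cell_id": c.cell_id, "vertices": list(c.vertex_ids)} for c in f.cells
                ],
            }
            for f in frames
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_mesh(path: str | Path) -> list[TissueFrame]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MESH_SCHEMA_VERSION:
        raise DataValidationError(
            f"unsupported mesh schema version {doc.get('schema_version')!r}"
        )
    frames = []
    for fr in doc["frames"]:
        verts = np.asarray(fr["vertices"], dtype=float)
        cell_vertices = {int(c["cell_id"]): [int(v) for v in c["vertices"]] for c in fr["cells"]}
        frames.append(
            TissueFrame.from_mesh(fr["frame_index"], fr["time_s"], verts, cell_vertices)
        )
    return frames


def save_traces(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"trace table missing columns {missing}")
    df.to_csv(path, index=False, columns=TRACE_COLUMNS)


def load_traces(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"junction_id": str, "channel": str})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"trace table missing columns {missing}")
    return df
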