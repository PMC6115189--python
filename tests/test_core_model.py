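"""Geometry primitives, junction classification and track assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcpdyn.circular import axial_mean_resultant
from pcpdyn.core_model import (
    JunctionTrack,
    build_tracks,
    cell_long_axis,
    classify_junction,
    load_mesh,
    save_mesh,
    segment_angle,
)
from pcpdyn.errors import DataValidationError, DegenerateGeometryError

finite = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)


# ---------------------------------------------------------------------------
# segment_angle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p0,p1,expected",
    [((0, 0), (4, 0), 0.0), ((0, 0), (0, 3), 90.0), ((0, 0), (1, 1), 45.0),
     ((2, 5), (-1, 5), 0.0), ((0, 0), (-1, 1), 45.0)],
)
def test_segment_angle_axial_values(p0, p1, expected):
    assert segment_angle(p0, p1) == pytest.approx(expected)


def test_segment_angle_coincident_endpoints_is_degenerate():
    with pytest.raises(DegenerateGeometryError):
        segment_angle((1.0, 2.0), (1.0, 2.0))


delta = st.floats(min_value=0.1, max_value=1e3).flatmap(
    lambda m: st.sampled_from([m, -m])
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(x0=finite, y0=finite, dx=delta, dy=delta, tx=finite, ty=finite)
def test_segment_angle_invariances(x0, y0, dx, dy, tx, ty):
    """Folded angle is in [0, 90], symmetric under endpoint swap, invariant
    under translation and reflection about either axis."""
    x1, y1 = x0 + dx, y0 + dy
    a = segment_angle((x0, y0), (x1, y1))
    assert 0.0 <= a <= 90.0
    assert segment_angle((x1, y1), (x0, y0)) == a
    assert segment_angle((x0 + tx, y0 + ty), (x1 + tx, y1 + ty)) == pytest.approx(a, abs=1e-5)
    assert segment_angle((-x0, y0), (-x1, y1)) == pytest.approx(a, abs=1e-9)
    assert segment_angle((x0, -y0), (x1, -y1)) == pytest.approx(a, abs=1e-9)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("angle,label", [(30.0, "V"), (46.0, "T"), (45.0, "V"),
                                         (0.0, "V"), (90.0, "T")])
def test_classify_junction_bins(angle, label):
    assert classify_junction(angle) == label


@pytest.mark.parametrize("angle", [-1.0, 90.5, 180.0])
def test_classify_junction_rejects_out_of_range(angle):
    with pytest.raises(DataValidationError):
        classify_junction(angle)


# ---------------------------------------------------------------------------
# cell long axis
# ---------------------------------------------------------------------------

def _rect(w, h, theta_deg=0.0):
    base = np.array([[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]])
    th = math.radians(theta_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return base @ rot.T + [3.0, 7.0]


def _pixel_covariance_axis(poly, n=400):
    """Brute-force oracle: covariance of a dense grid of points inside the
    polygon (uniform density), eigen-decomposed like the implementation."""
    from shapely.geometry import Polygon

    shp = Polygon(poly)
    minx, miny, maxx, maxy = shp.bounds
    xs = np.linspace(minx, maxx, n)
    ys = np.linspace(miny, maxy, n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    from shapely import contains_xy

    inside = contains_xy(shp, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, 1]
    angle = math.degrees(math.atan2(abs(vy), abs(vx)))
    return angle, math.sqrt(evals[1] / evals[0])


def test_long_axis_axis_aligned_rectangle():
    angle, aspect = cell_long_axis(_rect(4, 2))
    assert angle == pytest.approx(0.0, abs=1e-9)
    assert aspect == pytest.approx(2.0, rel=1e-9)


def test_long_axis_rotated_rectangle():
    angle, aspect = cell_long_axis(_rect(4, 2, 90.0))
    assert angle == pytest.approx(90.0, abs=1e-9)
    assert aspect == pytest.approx(2.0, rel=1e-9)


def test_long_axis_square_is_isotropic():
    angle, aspect = cell_long_axis(_rect(3, 3))
    assert math.isnan(angle)
    assert aspect == 1.0


@pytest.mark.parametrize("theta", [15.0, 37.0, 62.0])
def test_long_axis_matches_pixel_sampling_oracle(theta):
    poly = _rect(5, 2, theta)
    angle, aspect = cell_long_axis(poly)
    o_angle, o_aspect = _pixel_covariance_axis(poly)
    assert angle == pytest.approx(o_angle, abs=0.5)
    assert aspect == pytest.approx(o_aspect, rel=0.01)


def test_long_axis_degenerate_polygon_raises():
    with pytest.raises(DegenerateGeometryError):
        cell_long_axis(np.array([[0, 0], [1, 0], [2, 0]]))


# ---------------------------------------------------------------------------
# axial circular statistics
# ---------------------------------------------------------------------------

def test_axial_mean_identical_orientations():
    mean, r = axial_mean_resultant(np.array([0.0, 0.0, 0.0]))
    assert (mean, r) == (pytest.approx(0.0, abs=1e-9), pytest.approx(1.0))


def test_axial_mean_antipodal_pair_cancels():
    _, r = axial_mean_resultant(np.array([0.0, 90.0]))
    assert r == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=90), min_size=1, max_size=20))
def test_axial_resultant_in_unit_interval(angles):
    mean, r = axial_mean_resultant(np.array(angles))
    assert 0.0 <= r <= 1.0 + 1e-12
    assert 0.0 <= mean <= 90.0 + 1e-9


# ---------------------------------------------------------------------------
# frames and tracks
# ---------------------------------------------------------------------------

def test_polyline_arc_length_matches_length(control_sim):
    _, frames, _, _, _ = control_sim
    for j in frames[0].junctions:
        arc = float(np.linalg.norm(np.diff(j.polyline, axis=0), axis=1).sum())
        assert abs(arc - j.length_um) < 1e-9


def test_tracks_conserve_junction_occurrences(control_sim, control_tracks):
    _, frames, _, _, _ = control_sim
    total = sum(sum(1 for j in f.junctions if not j.is_boundary) for f in frames)
    assert sum(t.n_frames for t in control_tracks) == total


def test_static_frames_tracks_all_persist(static_sim):
    _, frames, _, _, _ = static_sim
    tracks = build_tracks(frames)
    assert all(t.fate == "persists" for t in tracks)
    assert all(t.n_frames == len(frames) for t in tracks)


def test_single_frame_tracks(static_sim):
    _, frames, _, _, _ = static_sim
    tracks = build_tracks(frames[:1])
    assert all(t.n_frames == 1 and t.fate == "persists" for t in tracks)


def test_planted_t1_produces_resolved_and_newly_formed_tracks(control_sim, control_tracks):
    cfg, _, gt, _, _ = control_sim
    by_id = {}
    for t in control_tracks:
        by_id.setdefault(t.junction_id, []).append(t)
    for ev in gt.t1_events:
        old = tuple(ev["pair"])
        new = tuple(ev["new_pair"])
        dying = [t for t in by_id[old] if t.fate == "resolved_T2"]
        assert len(dying) == 1
        assert dying[0].frames[-1] == ev["swap_frame"] - 1
        assert dying[0].length_series[-1] < cfg.eps_t2_um
        born = [t for t in by_id[new] if t.frames[0] >= ev["swap_frame"]]
        assert len(born) == 1 and born[0].fate in ("newly_formed", "resolved_T2")


def test_track_series_length_mismatch_rejected():
    with pytest.raises(DataValidationError):
        JunctionTrack(
            junction_id=(0, 1), frames=np.array([0, 1]), times_s=np.array([0.0]),
            length_series=np.array([1.0, 2.0]), angle_series=np.array([0.0, 0.0]),
        )


def test_mesh_json_round_trip(tmp_path, control_sim):
    _, frames, _, _, _ = control_sim
    path = tmp_path / "mesh.json"
    save_mesh(frames[:3], path)
    loaded = load_mesh(path)
    assert len(loaded) == 3
    for a, b in zip(frames[:3], loaded):
        ja = {j.junction_id: j.length_um for j in a.junctions}
        jb = {j.junction_id: j.length_um for j in b.junctions}
        assert ja.keys() == jb.keys()
        for k in ja:
            assert ja[k] == pytest.approx(jb[k], abs=1e-9)
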