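"""Temporal coupling of two junctional channels.

Pulsatile accumulation of a PCP protein and junctional myosin is analyzed
on frame-to-frame *changes* (delta-series), which removes the shared
shrinkage trend that would otherwise inflate the correlation: the key
readout is the lagged Pearson cross-correlation of the two delta-series,
averaged across junctions with SEM per lag.  A zero-lag peak indicates
synchronous accumulation dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import JunctionTrack
from .errors import DataValidationError

__all__ = [
    "DeltaSeries",
    "delta_series",
    "cross_correlation",
    "mean_cross_correlation",
    "intensity_length_coupling",
]


@dataclass
class DeltaSeries:
    """First differences of one junction-channel intensity trace."""

    junction_id: str
    channel: str
    dt_s: float
    values: np.ndarray  # length = trace length - 1


def delta_series(
    trace: np.ndarray,
    times_s: np.ndarray | None = None,
    *,
    junction_id: str = "",
    channel: str = "",
    dt_s: float | None = None,
    rtol: float = 1e-6,
) -> DeltaSeries:
    """First differences of a uniformly sampled trace.

    Raises on non-uniform sampling (resample upstream).
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise DataValidationError("delta series needs a trace of length >= 2")
    if times_s is not None:
        dts = np.diff(np.asarray(times_s, dtype=float))
        if np.any(np.abs(dts - dts[0]) > rtol * abs(dts[0])):
            raise DataValidationError("non-uniform sampling: resample before differencing")
        dt = float(dts[0])
    else:
        dt = float(dt_s) if dt_s is not None else 1.0
    return DeltaSeries(junction_id=junction_id, channel=channel, dt_s=dt, values=np.diff(x))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc * xc)) * np.sqrt(np.sum(yc * yc))
    if denom == 0.0:
        raise DataValidationError("constant series: correlation undefined")
    return float(np.clip(np.sum(xc * yc) / denom, -1.0, 1.0))


def cross_correlation(
    delta_a: DeltaSeries | np.ndarray,
    delta_b: DeltaSeries | np.ndarray,
    max_lag_frames: int = 5,
) -> pd.DataFrame:
    """Lagged Pearson correlation of two delta-series.

    rho(k) = corr(dA(t), dB(t + k)) over the overlapping frames, for
    k in [-max_lag, +max_lag].  Satisfies rho_AB(k) = rho_BA(-k) exactly.
    """
    a = delta_a.values if isinstance(delta_a, DeltaSeries) else np.asarray(delta_a, float)
    b = delta_b.values if isinstance(delta_b, DeltaSeries) else np.asarray(delta_b, float)
    n = min(len(a), len(b))
    rows = []
    for k in range(-max_lag_frames, max_lag_frames + 1):
        if k >= 0:
            xa, xb = a[: n - k] if k else a[:n], b[k:n]
        else:
            xa, xb = a[-k:n], b[: n + k]
        if len(xa) < 3:
            raise DataValidationError(
                f"lag {k}: overlap {len(xa)} < 3 samples; shorten max_lag"
            )
        rows.append({"lag_frames": k, "rho": _pearson(xa, xb), "n_overlap": len(xa)})
    return pd.DataFrame(rows)


def mean_cross_correlation(
    pairs: Sequence[tuple[DeltaSeries | np.ndarray, DeltaSeries | np.ndarray]],
    max_lag_frames: int = 5,
    dt_s: float | None = None,
) -> pd.DataFrame:
    """Across-junction mean +/- SEM of the per-junction cross-correlation.

    Each junction contributes its full-overlap correlation at every lag;
    junctions are averaged unweighted.  Output columns: lag_frames, lag_s
    (if dt known), mean_rho, sem, n.
    """
    if not pairs:
        raise DataValidationError("no delta-series pairs given")
    curves = []
    for da, db in pairs:
        c = cross_correlation(da, db, max_lag_frames)
        curves.append(c["rho"].to_numpy())
        if dt_s is None and isinstance(da, DeltaSeries):
            dt_s = da.dt_s
    mat = np.vstack(curves)
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    out = pd.DataFrame(
        {
            "lag_frames": lags,
            "lag_s": lags * (dt_s if dt_s is not None else np.nan),
            "mean_rho": mat.mean(axis=0),
            "sem": mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
            if mat.shape[0] > 1
            else np.zeros(len(lags)),
            "n": mat.shape[0],
        }
    )
    return out


# ---------------------------------------------------------------------------
# intensity / length co-variation
# ---------------------------------------------------------------------------

def intensity_length_coupling(
    tracks: Sequence[JunctionTrack],
    channel: str,
    *,
    normalize_by_membrane: bool = False,
    window_s: float | None = None,
    velocity_mode: bool = False,
    max_angle_deg: float = 30.0,
) -> tuple[pd.DataFrame, float, float]:
    """Per-track intensity change versus length change, with Spearman rho.

    Default mode: per track, delta L and delta I over the window (full track
    if ``window_s`` is None); optionally the channel intensity is divided by
    the membrane-channel intensity per frame first, to discount the passive
    density increase of a shrinking membrane.

    ``velocity_mode``: restricts to orientation-stable V-junctions (angle
    stays within ``max_angle_deg`` of the ML axis throughout) and correlates
    mean shrink velocity (um/min, positive = shrinking) with mean intensity.
    """
    rows = []
    skipped = 0
    for tr in tracks:
        if channel not in tr.intensity_series:
            continue
        inten = tr.intensity_series[channel].astype(float)
        if normalize_by_membrane:
            mem = tr.intensity_series.get("membrane")
            if mem is None:
                raise DataValidationError("membrane normalization requires a membrane channel")
            inten = inten / np.maximum(mem.astype(float), 1e-12)
        if np.any(np.isnan(inten)):
            continue
        if window_s is not None:
            mask = tr.times_s <= tr.times_s[0] + window_s
            if mask.sum() < 2:
                skipped += 1
                continue
        else:
            mask = np.ones(len(tr.times_s), dtype=bool)
        if mask.sum() < 2:
            skipped += 1
            continue
        idx = np.nonzero(mask)[0]
        k0, k1 = idx[0], idx[-1]
        if velocity_mode:
            if np.max(tr.angle_series) > max_angle_deg:
                continue
            span_min = (tr.times_s[k1] - tr.times_s[k0]) / 60.0
            if span_min <= 0:
                skipped += 1
                continue
            rows.append(
                {
                    "junction_id": f"{tr.junction_id[0]}-{tr.junction_id[1]}",
                    "shrink_velocity_um_per_min": float(
                        -(tr.length_series[k1] - tr.length_series[k0]) / span_min
                    ),
                    "mean_intensity": float(np.mean(inten[mask])),
                }
            )
        else:
            rows.append(
                {
                    "junction_id": f"{tr.junction_id[0]}-{tr.junction_id[1]}",
                    "delta_length_um": float(tr.length_series[k1] - tr.length_series[k0]),
                    "delta_intensity": float(inten[k1] - inten[k0]),
                }
            )
    table = pd.DataFrame(rows)
    if len(table) < 4:
        raise DataValidationError(
            f"intensity/length coupling needs >= 4 usable tracks (got {len(table)})"
        )
    if velocity_mode:
        x, y = table["shrink_velocity_um_per_min"], table["mean_intensity"]
    else:
        x, y = table["delta_length_um"], table["delta_intensity"]
    if x.nunique() < 2 or y.nunique() < 2:
        raise DataValidationError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return table, float(rho), float(p)
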