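"""FRAP normalization, recovery fitting and turnover-vs-behavior analysis.

Fluorescence recovery after photobleaching reports junctional protein
turnover: the fitted plateau recovery fraction M (mobile fraction) and its
complement 1 - M (nonmobile / stable fraction).  The analysis ties turnover
to junction behavior by classifying each bleached junction as shrinking
(length reduced by at least 0.5 um over bleaching + recovery) or
nonshrinking, and by regressing the nonmobile fraction on the length change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataValidationError, FitError

__all__ = [
    "SHRINK_THRESHOLD_UM",
    "FrapRecord",
    "FrapFit",
    "normalize_recovery",
    "fit_recovery",
    "classify_shrinking",
    "turnover_vs_behavior",
]

#: Length change (um) at or below which a bleached junction counts as shrinking.
SHRINK_THRESHOLD_UM = -0.5


@dataclass
class FrapFit:
    mobile_fraction: float
    tau_s: float
    plateau: float  # fitted F_inf on the normalized scale
    f0: float  # first post-bleach value (fixed unless fit_f0 is used)
    rss: float
    n_points: int
    clamped: bool = False
    tau_at_bound: bool = False


@dataclass
class FrapRecord:
    """One bleach experiment: raw traces, normalization, fit, behavior."""

    record_id: str
    junction_id: str
    times_s: np.ndarray
    t_bleach_s: float
    bleach_trace: np.ndarray
    reference_trace: np.ndarray
    background_trace: np.ndarray
    length_series_um: np.ndarray | None = None
    normalized_trace: np.ndarray | None = None
    fit: FrapFit | None = None
    planted_mobile_fraction: float | None = None
    planted_tau_s: float | None = None

    @property
    def delta_length_um(self) -> float:
        """Junction length change from the bleach frame to the last analyzed
        recovery frame."""
        if self.length_series_um is None:
            raise DataValidationError(f"{self.record_id}: no length series attached")
        i0 = int(np.searchsorted(self.times_s, self.t_bleach_s))
        return float(self.length_series_um[-1] - self.length_series_um[i0])

    @property
    def nonmobile_fraction(self) -> float:
        if self.fit is None:
            raise DataValidationError(f"{self.record_id}: recovery not fitted yet")
        return 1.0 - self.fit.mobile_fraction

    @property
    def shrink_class(self) -> str:
        return classify_shrinking(self.delta_length_um)


def classify_shrinking(delta_length_um: float) -> str:
    """'shrinking' iff the junction lost at least 0.5 um over bleach + recovery."""
    return "shrinking" if delta_length_um <= SHRINK_THRESHOLD_UM else "nonshrinking"


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_recovery(
    bleach_trace: np.ndarray,
    reference_trace: np.ndarray,
    background_trace: np.ndarray,
    times_s: np.ndarray,
    t_bleach_s: float,
) -> np.ndarray:
    """Double normalization of a bleach trace.

    F_norm(t) = [(I_bleach - bg) / (I_ref - bg)] / prebleach_mean(same ratio).

    Dividing by the background-subtracted unbleached reference cancels
    acquisition photofading; dividing by the pre-bleach mean of the ratio
    pins the pre-bleach level at 1.  Invariant to global intensity scaling
    and to any multiplicative fading shared by both traces.
    """
    b = np.asarray(bleach_trace, dtype=float)
    r = np.asarray(reference_trace, dtype=float)
    bg = np.asarray(background_trace, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if not (len(b) == len(r) == len(bg) == len(t)):
        raise DataValidationError("FRAP traces must share one time base")
    pre = t < t_bleach_s
    if pre.sum() < 2:
        raise DataValidationError("need >= 2 pre-bleach frames for normalization")
    ref_sub = r - bg
    if np.any(ref_sub <= 0):
        raise DataValidationError("non-positive reference after background subtraction")
    ratio = (b - bg) / ref_sub
    pre_mean = float(ratio[pre].mean())
    if pre_mean <= 0:
        raise DataValidationError("non-positive pre-bleach ratio")
    return ratio / pre_mean


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_recovery(
    normalized_trace: np.ndarray,
    times_s: np.ndarray,
    t_bleach_s: float,
    *,
    fit_f0: bool = False,
    tau_bounds: tuple[float, float] = (1e-3, 1e5),
) -> FrapFit:
    """Least-squares single-exponential recovery fit on post-bleach frames.

    F(t) = F0 + (F_inf - F0) * (1 - exp(-(t - t_bleach)/tau)), with F0 fixed
    to the first post-bleach value by default (reduces parameter covariance
    on short recoveries; set ``fit_f0=True`` to free it).  The mobile
    fraction is M = (F_inf - F0) / (F_pre - F0) with F_pre = 1 by
    construction of the normalization; M is clamped into [0, 1] with a
    warning if the fit strays outside.
    """
    f = np.asarray(normalized_trace, dtype=float)
    t = np.asarray(times_s, dtype=float)
    post = t >= t_bleach_s
    tp = t[post] - t_bleach_s
    fp = f[post]
    if len(fp) < 5:
        raise DataValidationError("need >= 5 post-bleach frames to fit recovery")
    f0 = float(fp[0])

    if np.allclose(fp, fp[0], atol=1e-12):
        # flat trace: no recovery at all
        return FrapFit(mobile_fraction=0.0, tau_s=float("nan"), plateau=f0, f0=f0,
                       rss=0.0, n_points=len(fp))

    finf_guess = float(fp[-1])
    # time at which ~63% of the apparent recovery is reached
    target = f0 + 0.632 * (finf_guess - f0)
    above = np.nonzero(fp >= target)[0] if finf_guess > f0 else np.nonzero(fp <= target)[0]
    tau_guess = float(tp[above[0]]) if len(above) and tp[above[0]] > 0 else max(tp[-1] / 5.0, 1e-2)

    try:
        if fit_f0:
            def model(tt, finf, tau, f0v):
                return f0v + (finf - f0v) * (1.0 - np.exp(-tt / tau))
            popt, _ = optimize.curve_fit(
                model, tp, fp, p0=[finf_guess, tau_guess, f0],
                bounds=([-np.inf, tau_bounds[0], -np.inf],
                        [np.inf, tau_bounds[1], np.inf]),
                maxfev=20000,
            )
            finf, tau, f0 = (float(v) for v in popt)
        else:
            def model(tt, finf, tau):
                return f0 + (finf - f0) * (1.0 - np.exp(-tt / tau))
            popt, _ = optimize.curve_fit(
                model, tp, fp, p0=[finf_guess, tau_guess],
                bounds=([-np.inf, tau_bounds[0]], [np.inf, tau_bounds[1]]),
                maxfev=20000,
            )
            finf, tau = float(popt[0]), float(popt[1])
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"recovery fit failed to converge: {exc}") from exc

    resid = fp - model(tp, *popt)
    rss = float(np.sum(resid**2))
    denom = 1.0 - f0
    mobile = (finf - f0) / denom if denom != 0 else 0.0
    clamped = False
    if mobile < 0.0 or mobile > 1.0:
        warnings.warn(
            f"mobile fraction {mobile:.3f} outside [0, 1]; clamped", stacklevel=2
        )
        mobile = float(np.clip(mobile, 0.0, 1.0))
        clamped = True
    tau_at_bound = bool(
        np.isclose(tau, tau_bounds[0], rtol=1e-6) or np.isclose(tau, tau_bounds[1], rtol=1e-6)
    )
    return FrapFit(mobile_fraction=float(mobile), tau_s=tau, plateau=finf, f0=f0,
                   rss=rss, n_points=len(fp), clamped=clamped, tau_at_bound=tau_at_bound)


def process_record(rec: FrapRecord, *, fit_f0: bool = False) -> FrapRecord:
    """Normalize and fit one record in place (returns it for chaining)."""
    rec.normalized_trace = normalize_recovery(
        rec.bleach_trace, rec.reference_trace, rec.background_trace,
        rec.times_s, rec.t_bleach_s,
    )
    rec.fit = fit_recovery(rec.normalized_trace, rec.times_s, rec.t_bleach_s, fit_f0=fit_f0)
    return rec


# ---------------------------------------------------------------------------
# population analysis
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

FRAP_COLUMNS = [
    "record_id", "frame", "time_s", "t_bleach_s", "bleach_intensity",
    "reference_intensity", "background_intensity", "junction_length_um",
]


def records_to_csv(records: list[FrapRecord], path) -> None:
    rows = []
    for r in records:
        for i, t in enumerate(r.times_s):
            rows.append(
                (r.record_id, i, float(t), r.t_bleach_s, float(r.bleach_trace[i]),
                 float(r.reference_trace[i]), float(r.background_trace[i]),
                 float(r.length_series_um[i]) if r.length_series_um is not None else np.nan)
            )
    pd.DataFrame(rows, columns=FRAP_COLUMNS).to_csv(path, index=False)


def records_from_csv(path) -> list[FrapRecord]:
    df = pd.read_csv(path, dtype={"record_id": str})
    missing = [c for c in FRAP_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"FRAP table missing columns {missing}")
    records = []
    for rid, grp in df.groupby("record_id", sort=True):
        grp = grp.sort_values("frame")
        lengths = grp["junction_length_um"].to_numpy(dtype=float)
        records.append(
            FrapRecord(
                record_id=str(rid),
                junction_id=str(rid),
                times_s=grp["time_s"].to_numpy(dtype=float),
                t_bleach_s=float(grp["t_bleach_s"].iloc[0]),
                bleach_trace=grp["bleach_intensity"].to_numpy(dtype=float),
                reference_trace=grp["reference_intensity"].to_numpy(dtype=float),
                background_trace=grp["background_intensity"].to_numpy(dtype=float),
                length_series_um=None if np.all(np.isnan(lengths)) else lengths,
            )
        )
    return records


@dataclass
class TurnoverResult:
    table: pd.DataFrame  # per record: delta_length_um, nonmobile_fraction, shrink_class
    group_time_s: np.ndarray
    group_curves: dict[str, dict[str, np.ndarray]]  # class -> {mean, sem, n}
    regression_slope: float
    regression_intercept: float
    spearman_rho: float
    spearman_p: float
    warnings: list[str] = field(default_factory=list)


def turnover_vs_behavior(
    records: list[FrapRecord], *, n_grid: int = 50, fit_f0: bool = False
) -> TurnoverResult:
    """Classwise mean recovery curves and nonmobile-fraction-vs-length-change
    statistics over a cohort of bleach experiments.

    Group curves are averaged on a common post-bleach time grid (the
    intersection of the records' post-bleach spans, linear interpolation);
    the per-record table carries (delta L, nonmobile fraction), and the
    summary includes the linear regression of nonmobile fraction on delta L
    and the Spearman correlation.
    """
    if not records:
        raise DataValidationError("no FRAP records given")
    notes: list[str] = []
    for rec in records:
        if rec.fit is None:
            process_record(rec, fit_f0=fit_f0)
    rows = [
        {
            "record_id": r.record_id,
            "delta_length_um": r.delta_length_um,
            "nonmobile_fraction": r.nonmobile_fraction,
            "mobile_fraction": r.fit.mobile_fraction,
            "tau_s": r.fit.tau_s,
            "shrink_class": r.shrink_class,
        }
        for r in records
    ]
    table = pd.DataFrame(rows)

    # common post-bleach grid
    t_end = min(float(r.times_s[-1] - r.t_bleach_s) for r in records)
    grid = np.linspace(0.0, t_end, n_grid)
    group_curves: dict[str, dict[str, np.ndarray]] = {}
    for cls in ("shrinking", "nonshrinking"):
        members = [r for r in records if r.shrink_class == cls]
        if len(members) < 2:
            notes.append(f"group curve omitted for class {cls!r}: n={len(members)} < 2")
            continue
        mat = np.vstack([
            np.interp(
                grid,
                r.times_s[r.times_s >= r.t_bleach_s] - r.t_bleach_s,
                r.normalized_trace[r.times_s >= r.t_bleach_s],
            )
            for r in members
        ])
        group_curves[cls] = {
            "mean": mat.mean(axis=0),
            "sem": mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]),
            "n": np.full(n_grid, mat.shape[0]),
        }

    dl = table["delta_length_um"].to_numpy()
    nm = table["nonmobile_fraction"].to_numpy()
    if len(records) < 2 or np.allclose(dl, dl[0]):
        slope, intercept = 0.0, float(nm.mean())
    else:
        slope, intercept = np.polyfit(dl, nm, 1)
    if np.allclose(nm, nm[0]) or np.allclose(dl, dl[0]):
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(dl, nm)
    return TurnoverResult(
        table=table, group_time_s=grid, group_curves=group_curves,
        regression_slope=float(slope), regression_intercept=float(intercept),
        spearman_rho=float(rho), spearman_p=float(p), warnings=notes,
    )


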