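"""Population-level planar-polarity statistics.

Quantifies asymmetric junctional enrichment of a labeled protein (a core
PCP component or myosin): per-junction enrichment ratios, V- vs T-class
comparison (Mann-Whitney), the correlation between enrichment and junction
orientation (Spearman), and the Fisher r-to-z contrast used to compare the
orientation correlation between experimental regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import axial_mean_deg
from .core_model import classify_junction, parse_junction_id
from .errors import DataValidationError

__all__ = [
    "normalize_enrichment",
    "remove_outliers",
    "compare_classes",
    "angle_correlation",
    "compare_correlations",
    "build_polarity_table",
    "ClassComparison",
]

#: switch point below which Mann-Whitney uses full enumeration
EXACT_MW_MAX_N = 8

#: outlier threshold in sample standard deviations
OUTLIER_Z = 3.0


def normalize_enrichment(
    junction_intensity: float,
    context: dict,
    mode: str = "cytoplasm",
) -> float:
    """Junctional enrichment ratio.

    ``mode='cytoplasm'``: junction mean divided by the unweighted mean of the
    cytoplasmic means of the two cells sharing the junction (``context``
    needs ``cytoplasm_a`` and, for interior junctions, ``cytoplasm_b``).
    Boundary junctions with a single cell use that cell alone; callers flag
    and usually exclude them.

    ``mode='membrane'``: the channel's junction mean divided by the
    membrane-channel mean on the same pixels/frames (``context`` needs
    ``membrane``).
    """
    if mode == "cytoplasm":
        ca = context.get("cytoplasm_a")
        cb = context.get("cytoplasm_b")
        if ca is None:
            raise DataValidationError("cytoplasm mode requires cytoplasm_a")
        denom = float(ca) if cb is None else (float(ca) + float(cb)) / 2.0
    elif mode == "membrane":
        if context.get("membrane") is None:
            raise DataValidationError("membrane mode requires the membrane-channel mean")
        denom = float(context["membrane"])
    else:
        raise DataValidationError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise DataValidationError(f"non-positive normalization denominator {denom!r}")
    return float(junction_intensity) / denom


def remove_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of values more than 3 SD from the sample mean.

    The mean and SD come from the full sample (no iteration).  An all-equal
    sample (SD 0) removes nothing.  Returns (kept values, removed indices).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DataValidationError("outlier removal needs n >= 3")
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return v.copy(), np.array([], dtype=int)
    z = np.abs(v - v.mean()) / sd
    removed = np.nonzero(z > OUTLIER_Z)[0]
    kept = np.delete(v, removed)
    return kept, removed


@dataclass
class ClassComparison:
    v_mean: float
    v_sd: float
    v_n: int
    t_mean: float
    t_sd: float
    t_n: int
    u_statistic: float
    p_value: float
    method: str


def compare_classes(v_values: np.ndarray, t_values: np.ndarray) -> ClassComparison:
    """Mann-Whitney comparison of V- and T-class enrichment values.

    Exact p when min(n, m) <= 8 and the pooled sample is tie-free (where the
    exact null is well defined); tie-corrected normal approximation
    otherwise, matching standard practice.
    """
    v = np.asarray(v_values, dtype=float)
    t = np.asarray(t_values, dtype=float)
    if v.size == 0 or t.size == 0:
        raise DataValidationError("both junction classes must be non-empty")
    pooled = np.concatenate([v, t])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(v.size, t.size) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(v, t, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(v, t, alternative="two-sided", method="asymptotic")
    return ClassComparison(
        v_mean=float(v.mean()), v_sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        v_n=int(v.size),
        t_mean=float(t.mean()), t_sd=float(t.std(ddof=1)) if t.size > 1 else 0.0,
        t_n=int(t.size),
        u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method,
    )


def angle_correlation(
    angles_deg: np.ndarray, enrichment: np.ndarray
) -> tuple[float, float, int]:
    """Spearman rank correlation of enrichment against junction orientation.

    Returns (rho, two-sided p, n).  Tie-averaged ranks.  Raises if either
    input is constant (the correlation is undefined).
    """
    a = np.asarray(angles_deg, dtype=float)
    e = np.asarray(enrichment, dtype=float)
    if a.size != e.size or a.size < 4:
        raise DataValidationError("angle correlation needs >= 4 paired observations")
    if np.all(a == a[0]) or np.all(e == e[0]):
        raise DataValidationError("constant input: correlation undefined")
    rho, p = stats.spearmanr(a, e)
    return float(rho), float(p), int(a.size)


def compare_correlations(
    rho1: float, n1: int, rho2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z contrast of two independent correlation coefficients.

    z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p
    from the standard normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise DataValidationError("Fisher r-to-z needs n > 3 in both samples")
    if abs(rho1) >= 1.0 or abs(rho2) >= 1.0:
        raise DataValidationError("|rho| = 1: Fisher transform is infinite")
    z = (math.atanh(rho1) - math.atanh(rho2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_polarity_table(
    traces: pd.DataFrame,
    cytoplasm: pd.DataFrame | None,
    channel: str,
    *,
    mode: str = "cytoplasm",
    regime_label: str = "control",
    drop_outliers: bool = True,
    at_frame: int | str | None = "first",
) -> pd.DataFrame:
    """Per-junction enrichment table from long-format trace tables.

    Each junction contributes one row: its raw intensity in ``channel``,
    its orientation, its V/T class, and its normalized enrichment
    (cytoplasm mode: against the time-averaged cytoplasmic means of the two
    cells sharing the junction; membrane mode: against the membrane channel
    on the same junction/frames).  ``at_frame`` selects the measurement
    time point per junction: ``"first"`` (default) measures each junction
    once, at its first observed frame — the still-image procedure, which
    keeps the baseline polarity estimate free of the dynamic
    shrinkage-coupled intensity component; an integer restricts to that
    frame; ``None`` averages over all frames.  Boundary junctions (single
    adjacent cell) are excluded.  Extreme enrichment outliers (>3 SD) are
    removed in a single pass when ``drop_outliers``.
    """
    ch = traces[traces["channel"] == channel]
    if ch.empty:
        raise DataValidationError(f"channel {channel!r} absent from trace table")
    if at_frame == "first":
        first = ch.groupby("junction_id")["frame"].transform("min")
        ch = ch[ch["frame"] == first]
    elif at_frame is not None:
        ch = ch[ch["frame"] == int(at_frame)]
        if ch.empty:
            raise DataValidationError(f"no junctions measured at frame {at_frame}")
    cyto_mean: dict[int, float] = {}
    if cytoplasm is not None:
        sub = cytoplasm[cytoplasm["channel"] == channel]
        cyto_mean = sub.groupby("cell_id")["mean_intensity"].mean().to_dict()

    mem_mean: dict[str, float] = {}
    if mode == "membrane":
        mem = traces[traces["channel"] == "membrane"]
        if mem.empty:
            raise DataValidationError("membrane mode requires a membrane channel")
        if at_frame == "first":
            mfirst = mem.groupby("junction_id")["frame"].transform("min")
            mem = mem[mem["frame"] == mfirst]
        elif at_frame is not None:
            mem = mem[mem["frame"] == int(at_frame)]
        mem_mean = mem.groupby("junction_id")["mean_intensity"].mean().to_dict()

    rows = []
    for jid_str, grp in ch.groupby("junction_id"):
        a, b = parse_junction_id(jid_str)
        if a < 0 or b < 0:
            continue  # boundary junction: flagged out of population statistics
        raw = float(grp["mean_intensity"].mean())
        angle = axial_mean_deg(grp["angle_deg"].to_numpy())
        if mode == "cytoplasm":
            if a not in cyto_mean and b not in cyto_mean:
                raise DataValidationError(f"no cytoplasm measurements for junction {jid_str}")
            ca = cyto_mean.get(a)
            cb = cyto_mean.get(b)
            context = {"cytoplasm_a": ca if ca is not None else cb,
                       "cytoplasm_b": cb if ca is not None else None}
        else:
            context = {"membrane": mem_mean.get(jid_str)}
        enr = normalize_enrichment(raw, context, mode=mode)
        rows.append(
            {"junction_id": jid_str, "angle_deg": angle,
             "class_label": classify_junction(angle), "raw_intensity": raw,
             "normalization_mode": mode, "normalized_enrichment": enr,
             "regime_label": regime_label}
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise DataValidationError("no interior junctions in trace table")
    if drop_outliers and len(table) >= 3:
        _, removed = remove_outliers(table["normalized_enrichment"].to_numpy())
        if len(removed):
            table = table.drop(table.index[removed]).reset_index(drop=True)
    return table


def polarity_report(table: pd.DataFrame) -> dict:
    """Summary statistics of one polarity table (means, U test, rho)."""
    v = table.loc[table["class_label"] == "V", "normalized_enrichment"].to_numpy()
    t = table.loc[table["class_label"] == "T", "normalized_enrichment"].to_numpy()
    cmp_ = compare_classes(v, t)
    rho, p, n = angle_correlation(
        table["angle_deg"].to_numpy(), table["normalized_enrichment"].to_numpy()
    )
    return {
        "v_mean": cmp_.v_mean, "v_sd": cmp_.v_sd, "n_v": cmp_.v_n,
        "t_mean": cmp_.t_mean, "t_sd": cmp_.t_sd, "n_t": cmp_.t_n,
        "vt_ratio": cmp_.v_mean / cmp_.t_mean if cmp_.t_mean else float("nan"),
        "mannwhitney_u": cmp_.u_statistic, "mannwhitney_p": cmp_.p_value,
        "mannwhitney_method": cmp_.method,
        "angle_rho": rho, "angle_rho_p": p, "n_junctions": n,
    }
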