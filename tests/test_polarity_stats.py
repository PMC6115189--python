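"""Enrichment normalization and population polarity statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pcpdyn.errors import DataValidationError
from pcpdyn.polarity_stats import (
    angle_correlation,
    build_polarity_table,
    compare_classes,
    compare_correlations,
    normalize_enrichment,
    polarity_report,
    remove_outliers,
)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "junction,context,mode,expected",
    [
        (200.0, {"cytoplasm_a": 100.0, "cytoplasm_b": 100.0}, "cytoplasm", 2.0),
        (150.0, {"membrane": 150.0}, "membrane", 1.0),
        (200.0, {"cytoplasm_a": 50.0, "cytoplasm_b": 150.0}, "cytoplasm", 2.0),
        (120.0, {"cytoplasm_a": 60.0, "cytoplasm_b": None}, "cytoplasm", 2.0),
    ],
)
def test_normalize_enrichment(junction, context, mode, expected):
    assert normalize_enrichment(junction, context, mode) == pytest.approx(expected)


def test_normalize_enrichment_rejects_bad_denominator():
    with pytest.raises(DataValidationError):
        normalize_enrichment(100.0, {"cytoplasm_a": 0.0, "cytoplasm_b": 0.0}, "cytoplasm")
    with pytest.raises(DataValidationError):
        normalize_enrichment(100.0, {}, "cytoplasm")
    with pytest.raises(DataValidationError):
        normalize_enrichment(100.0, {"membrane": 1.0}, "no-such-mode")


# ---------------------------------------------------------------------------
# outlier removal
# ---------------------------------------------------------------------------

def test_remove_outliers_single_extreme_value():
    values = np.concatenate([np.full(100, 1.0), [50.0]])
    # direct oracle: |z| of the 50 under the full-sample mean/SD
    z = abs(50.0 - values.mean()) / values.std(ddof=1)
    assert z > 3
    kept, removed = remove_outliers(values)
    assert list(removed) == [100]
    assert len(kept) == 100


def test_remove_outliers_all_equal_sample_keeps_everything():
    kept, removed = remove_outliers(np.full(10, 2.5))
    assert removed.size == 0 and len(kept) == 10


def test_remove_outliers_normal_sample_rate(rng):
    """Under normality ~0.27% of draws sit beyond 3 SD."""
    values = rng.normal(0, 1, 1000)
    _, removed = remove_outliers(values)
    assert 0 <= removed.size <= 12  # Poisson(2.7), generous upper bound


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _mannwhitney_enumeration_p(v, t):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([v, t])
    n = len(v)
    u_obs = stats.mannwhitneyu(v, t, alternative="two-sided").statistic
    m = len(pooled) - n
    u_all = []
    for comb in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = 0.0
        for a in pooled[mask]:
            u += np.sum(a > pooled[~mask]) + 0.5 * np.sum(a == pooled[~mask])
        u_all.append(u)
    u_all = np.array(u_all)
    mu = n * m / 2.0
    return float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12))


def test_compare_classes_exact_small_sample():
    res = compare_classes(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
    assert res.u_statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements as extreme
    assert res.method == "exact"


def test_compare_classes_matches_enumeration(rng):
    v = rng.normal(0, 1, 5)
    t = rng.normal(0.5, 1, 6)
    res = compare_classes(v, t)
    assert res.p_value == pytest.approx(_mannwhitney_enumeration_p(v, t), abs=1e-12)


def test_compare_classes_identical_multisets():
    res = compare_classes(np.array([1.0, 2.0, 3.0, 4.0] * 5), np.array([1.0, 2.0, 3.0, 4.0] * 5))
    assert res.p_value > 0.9
    assert res.method == "asymptotic"  # ties force the tie-corrected approximation


def test_compare_classes_empty_class_rejected():
    with pytest.raises(DataValidationError):
        compare_classes(np.array([]), np.array([1.0]))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_angle_correlation_perfect_monotone():
    angles = np.linspace(0, 90, 20)
    rho, p, n = angle_correlation(angles, 10.0 - angles / 10.0)
    assert rho == pytest.approx(-1.0)
    assert n == 20


def test_angle_correlation_matches_rank_formula(rng):
    """Definitional oracle: Pearson correlation of tie-averaged ranks."""
    angles = rng.uniform(0, 90, 20)
    enr = rng.uniform(0.5, 3.0, 20)
    rho, _, _ = angle_correlation(angles, enr)
    ra = stats.rankdata(angles)
    re = stats.rankdata(enr)
    oracle = np.corrcoef(ra, re)[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_angle_correlation_constant_input_rejected():
    with pytest.raises(DataValidationError):
        angle_correlation(np.full(10, 45.0), np.arange(10.0))


def test_compare_correlations_direct_formula():
    z, p = compare_correlations(0.5, 103, 0.0, 103)
    assert z == pytest.approx(math.atanh(0.5) / math.sqrt(2.0 / 100.0), abs=1e-12)
    assert z == pytest.approx(3.884, abs=1e-3)
    z0, p0 = compare_correlations(0.3, 50, 0.3, 70)
    assert z0 == 0.0 and p0 == pytest.approx(1.0)
    z_swap, _ = compare_correlations(0.0, 103, 0.5, 103)
    assert z_swap == pytest.approx(-z, abs=1e-15)
    with pytest.raises(DataValidationError):
        compare_correlations(1.0, 10, 0.0, 10)


# ---------------------------------------------------------------------------
# planted regimes through the table builder
# ---------------------------------------------------------------------------

def test_control_table_recovers_planted_polarity(control_sim):
    _, _, _, traces, cyto = control_sim
    table = build_polarity_table(traces, cyto, "pcp")
    rep = polarity_report(table)
    assert rep["v_mean"] > rep["t_mean"]
    assert rep["mannwhitney_p"] < 1e-4
    assert rep["angle_rho"] < -0.5
    assert (table["class_label"] == (table["angle_deg"] > 45).map({True: "T", False: "V"})).all()
    assert (table["normalized_enrichment"] > 0).all()


def test_flat_regime_correlation_indistinguishable_from_zero():
    from pcpdyn.synthetic_tissue import SimConfig, generate_intensities, generate_tissue

    cfg = SimConfig(
        n_cells=64, n_frames=6, seed=13, enrichment_V=1.4, enrichment_T=1.4,
        convergence_rate_per_s=0.0, n_t1_events=0, n_rosettes=0,
    )
    frames, gt = generate_tissue(cfg)
    traces, cyto = generate_intensities(frames, gt, cfg)
    rep = polarity_report(build_polarity_table(traces, cyto, "pcp"))
    assert abs(rep["angle_rho"]) < 0.25
    assert rep["angle_rho_p"] > 0.01


def test_membrane_mode_normalization(control_sim):
    _, _, _, traces, cyto = control_sim
    table = build_polarity_table(traces, None, "pcp", mode="membrane")
    # membrane baseline is 1.0, so membrane-normalized PCP enrichment stays
    # close to the cytoplasm-normalized planted values
    v = table.loc[table.class_label == "V", "normalized_enrichment"].mean()
    t = table.loc[table.class_label == "T", "normalized_enrichment"].mean()
    assert v > 1.5 * t
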