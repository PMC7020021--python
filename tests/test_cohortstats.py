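"""Ratios, regression, normative comparison, ICC, normality, labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cheekmorph import cohortstats
from cheekmorph.cohortstats import (fit_prediction_model,
                                    icc_absolute_agreement, ks_normality,
                                    multiple_correlation, norm_comparison,
                                    norm_comparison_from_summary,
                                    pearson_strength_label, side_comparison,
                                    soft_bone_ratio)


def make_table(y, x1, x2=None, sides=None, cheek=None):
    n = len(y)
    x2 = np.zeros(n) if x2 is None else np.asarray(x2, float)
    sides = (["R", "L"] * n)[:n] if sides is None else sides
    patients = [f"P{i // 2:03d}" for i in range(n)]
    return pd.DataFrame({
        "patient": patients, "side": sides,
        "soft_movement": np.asarray(y, float),
        "bone_advancement": np.asarray(x1, float),
        "rotation": x2,
        "cheek_mass_position": np.zeros(n) if cheek is None else cheek,
        "stratum": ["2-3 mm"] * n,
    })


# ---------------------------------------------------------------- ratios

def test_ratio_unity_and_exact_halves():
    t = make_table([2.0, 3.0], [2.0, 3.0])
    r = soft_bone_ratio(t)
    assert r.loc["Total", "mean"] == pytest.approx(1.0)
    assert r.loc["Total", "sd"] == pytest.approx(0.0)
    t = make_table([1.0, 2.0], [2.0, 4.0])
    r = soft_bone_ratio(t)
    assert r.loc["Total", "mean"] == pytest.approx(0.5)
    assert r.loc["Total", "sd"] == pytest.approx(0.0)


def test_ratio_rejects_zero_bone_movement():
    t = make_table([1.0, 2.0], [2.0, 0.0])
    with pytest.raises(ValueError, match="non-positive"):
        soft_bone_ratio(t)


# ---------------------------------------------------- side comparison

def test_side_comparison_identical_sides():
    y = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 1.5, 1.5]
    t = make_table(y, np.ones(8), sides=["R", "L"] * 4)
    tstat, p = side_comparison(t, "soft_movement")
    assert tstat == 0.0 and p == 1.0


def test_side_comparison_matches_paired_t_oracle():
    rng = np.random.default_rng(0)
    r = rng.normal(2, 0.5, 6)
    l = r + rng.normal(0.1, 0.2, 6)
    y = np.empty(12)
    y[0::2], y[1::2] = r, l
    t = make_table(y, np.ones(12), sides=["R", "L"] * 6)
    tstat, p = side_comparison(t, "soft_movement")
    # textbook paired-t formula
    d = r - l
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
    assert tstat == pytest.approx(t_oracle, abs=1e-9)
    assert p == pytest.approx(p_oracle, abs=1e-9)


# ---------------------------------------------------------- regression

def test_noiseless_model_recovered_exactly():
    rng = np.random.default_rng(1)
    x1 = rng.uniform(1, 5, 24)
    x2 = rng.uniform(0, 8, 24)
    y = 0.6 * x1 + 0.1 * x2
    m = fit_prediction_model(make_table(y, x1, x2), "Total")
    assert m.b1 == pytest.approx(0.6, abs=1e-9)
    assert m.b2 == pytest.approx(0.1, abs=1e-9)
    assert m.r_squared == pytest.approx(1.0, abs=1e-9)
    assert multiple_correlation(m) == pytest.approx(1.0, abs=1e-9)


def test_single_predictor_identity_line():
    x1 = np.arange(1.0, 13.0)
    m = fit_prediction_model(make_table(x1, x1), "Total")
    assert m.b1 == pytest.approx(1.0, abs=1e-12)
    assert m.b2 == pytest.approx(0.0, abs=1e-12)


def test_coefficients_match_normal_equations_oracle():
    """Zero-intercept least squares equals the explicit 2×2 solve."""
    rng = np.random.default_rng(2)
    for _ in range(10):
        x1 = rng.uniform(1, 5, 30)
        x2 = rng.uniform(0, 8, 30)
        y = 0.6 * x1 + 0.1 * x2 + rng.normal(0, 0.3, 30)
        X = np.column_stack([x1, x2])
        b_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        m = fit_prediction_model(make_table(y, x1, x2), "Total")
        assert np.allclose([m.b1, m.b2], b_oracle, atol=1e-10)
        assert 0.0 <= m.r_squared <= 1.0
        assert all(0.0 <= p <= 1.0 for p in m.partial_r_squared)


def test_multiple_correlation_of_published_r_squared():
    """r = sqrt(R²): the published 0.788 corresponds to r ≈ 0.888–0.890."""
    from cheekmorph.cohortstats import PredictionModel
    pm = PredictionModel(region="Total", b1=0.627, b2=0.070, intercept=0.0,
                         r_squared=0.788, partial_r_squared=(0.432, 0.043),
                         p_values=(0.0, 0.0), interaction_p=None, n=96)
    assert multiple_correlation(pm) == pytest.approx(0.8877, abs=5e-4)
    pm0 = PredictionModel(region="Total", b1=0, b2=0, intercept=0,
                          r_squared=0.0, partial_r_squared=(0, 0),
                          p_values=(1, 1), interaction_p=None, n=96)
    assert multiple_correlation(pm0) == 0.0


def test_collinear_predictors_raise():
    x1 = np.linspace(1, 5, 12)
    with pytest.raises(ValueError, match="collinear"):
        fit_prediction_model(make_table(x1, x1, 2 * x1), "Total")


# ------------------------------------------------- normative comparison

def test_norm_difference_is_group_minus_norm():
    c = norm_comparison_from_summary("2-3 mm", 1.491, 0.607, 34)
    assert c.difference == pytest.approx(1.491 - 2.145, abs=1e-12)


def test_identical_summaries_give_p_one():
    c = norm_comparison_from_summary("x", 2.145, 1.201, 60, 2.145, 1.201, 60)
    assert c.t_statistic == pytest.approx(0.0, abs=1e-12)
    assert c.p_value == pytest.approx(1.0, abs=1e-12)


def test_welch_matches_summary_statistics_oracle():
    """Welch t and df from the textbook formulas."""
    m1, s1, n1 = 1.7, 0.6, 20
    m2, s2, n2 = 2.145, 1.201, 60
    c = norm_comparison_from_summary("x", m1, s1, n1, m2, s2, n2)
    se2 = s1 ** 2 / n1 + s2 ** 2 / n2
    t_oracle = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((s1 ** 2 / n1) ** 2 / (n1 - 1)
                     + (s2 ** 2 / n2) ** 2 / (n2 - 1))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), df)
    assert c.t_statistic == pytest.approx(t_oracle, abs=1e-9)
    assert c.p_value == pytest.approx(p_oracle, abs=1e-9)


def test_norm_comparison_from_cohort_table():
    vals = np.array([1.0, 1.4, 1.8, 2.2])
    t = make_table(np.ones(4), np.ones(4), cheek=vals)
    c = norm_comparison(t, "2-3 mm")
    assert c.group_mean == pytest.approx(vals.mean())
    assert c.difference == pytest.approx(vals.mean() - 2.145)
    with pytest.raises(ValueError):
        norm_comparison(t, ">4 mm")


# ------------------------------------------------------------------ ICC

def test_icc_duplicated_ratings_is_one():
    x = np.array([1.0, 2.0, 3.5, 4.2, 5.1, 6.0])
    assert icc_absolute_agreement(np.vstack([x, x])) == pytest.approx(1.0)


def test_icc_shift_invariance_and_errors():
    rng = np.random.default_rng(3)
    R = rng.normal(0, 1, (2, 8))
    base = icc_absolute_agreement(R)
    assert icc_absolute_agreement(R + 5.0) == pytest.approx(base, abs=1e-12)
    with pytest.raises(ValueError):
        icc_absolute_agreement(np.ones((2, 8)))
    with pytest.raises(ValueError):
        icc_absolute_agreement(np.zeros((1, 8)))


def test_icc_variance_components_construction():
    """Targets with variance 9× the rater noise give ICC ≈ 0.9."""
    rng = np.random.default_rng(4)
    targets = rng.normal(0, 3.0, 500)
    ratings = np.vstack([targets + rng.normal(0, 1.0, 500),
                         targets + rng.normal(0, 1.0, 500)])
    assert icc_absolute_agreement(ratings) == pytest.approx(0.9, abs=0.03)


def test_icc_matches_hand_computed_anova_oracle():
    """2 raters × 6 targets worked example against the mean-squares route."""
    R = np.array([[9.0, 6.0, 8.0, 7.0, 10.0, 6.0],
                  [2.0, 1.0, 4.0, 1.0, 5.0, 2.0]])
    k, n = R.shape
    grand = R.mean()
    msr = k * np.sum((R.mean(axis=0) - grand) ** 2) / (n - 1)
    msc = n * np.sum((R.mean(axis=1) - grand) ** 2) / (k - 1)
    mse = (np.sum((R - grand) ** 2)
           - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    icc_oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert icc_absolute_agreement(R) == pytest.approx(icc_oracle, abs=1e-9)


def test_icc_matches_pingouin_icc2():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    targets = rng.normal(5, 2, 12)
    R = np.vstack([targets + rng.normal(0, 0.5, 12),
                   targets + rng.normal(0.3, 0.5, 12)])
    long = pd.DataFrame({
        "targets": np.tile(np.arange(12), 2),
        "raters": np.repeat(["A", "B"], 12),
        "ratings": R.ravel(),
    })
    icc2 = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                    ratings="ratings")
    # single-measure absolute agreement = ICC(A,1) in pingouin's table
    expected = float(icc2.loc[icc2["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert icc_absolute_agreement(R) == pytest.approx(expected, abs=1e-9)


# -------------------------------------------------------------- KS test

def test_ks_normality_behaviour():
    with pytest.raises(ValueError):
        ks_normality([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        ks_normality(np.full(10, 3.3))
    # values placed at exact normal quantiles give a small statistic
    q = stats.norm.ppf((np.arange(1, 41) - 0.5) / 40)
    stat, p = ks_normality(q)
    assert stat < 0.05
    assert p > 0.9
    # calibration: false-positive rate of the asymptotic p at the 5 % level
    rng = np.random.default_rng(6)
    rejections = sum(ks_normality(rng.normal(0, 1, 80))[1] < 0.05
                     for _ in range(200))
    assert rejections <= 20  # asymptotic p is conservative at this n


# --------------------------------------------------------------- labels

@pytest.mark.parametrize("r,label", [
    (0.1, "weak"), (-0.2, "weak"),
    (0.3, "moderate"), (0.45, "moderate"),
    (0.6, "strong"), (0.8, "strong"),
    (0.89, "extremely strong"), (-0.95, "extremely strong"),
])
def test_pearson_strength_labels(r, label):
    assert pearson_strength_label(r) == label


def test_pearson_label_rejects_invalid_r():
    with pytest.raises(ValueError):
        pearson_strength_label(1.2)
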