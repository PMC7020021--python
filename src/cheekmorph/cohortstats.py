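"""Cohort-level statistics: ratios, prediction models, normative comparison.

Works on a tidy per-(patient, side) table with columns

``patient, side, soft_movement, bone_advancement, rotation,
cheek_mass_position, stratum``

(mm / degrees throughout).  The centrepiece is the zero-intercept multiple
regression of the soft-tissue sagittal movement Y on the bone advancement X1
(mm) and rotation X2 (degrees),

    Y = b1·X1 + b2·X2,

with R² reported as the squared Pearson correlation between observed and
fitted Y and per-predictor partial R² as the squared partial correlation
given the other predictor.  Supporting analyses: per-side soft/bone movement
ratios, paired left-right comparisons, Welch t-tests of stratified cheek
mass position against a published normative mean/SD/n, two-way random
absolute-agreement ICC for landmark reliability, and Kolmogorov–Smirnov
normality screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cheekmetric import NORM_MEAN_MM, NORM_N, NORM_SD_MM
from .volumetrics import STRATUM_LABELS

#: Columns required in a cohort table.
COHORT_COLUMNS = ("patient", "side", "soft_movement", "bone_advancement",
                  "rotation", "cheek_mass_position", "stratum")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (table["bone_advancement"] <= 0).any():
        bad = table.loc[table["bone_advancement"] <= 0].index.tolist()
        raise ValueError(f"non-positive bone advancement in records {bad}")
    return table


@dataclass(frozen=True)
class PredictionModel:
    """Fitted soft-tissue movement model for one cheek region."""

    region: str
    b1: float                       # mm soft per mm advancement
    b2: float                       # mm soft per degree rotation
    intercept: float                # 0 unless fitted with an intercept
    r_squared: float                # corr(Y, fitted)²
    partial_r_squared: Tuple[float, float]  # (X1 | X2), (X2 | X1)
    p_values: Tuple[float, float]
    interaction_p: Optional[float]  # advancement×rotation term, if requested
    n: int


@dataclass(frozen=True)
class NormComparison:
    """One stratum of cheek mass position against the normative cohort."""

    stratum: str
    group_mean: float
    group_sd: float
    group_n: int
    norm_mean: float
    norm_sd: float
    norm_n: int
    difference: float     # group mean − norm mean
    t_statistic: float
    p_value: float


def soft_bone_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Per-record soft/bone movement ratio, summarized by side and pooled.

    Returns a frame indexed by "Right", "Left", "Total" with columns
    ``mean``, ``sd``, ``n`` (SD with n−1 denominator; zero for n = 1).
    """
    t = validate_cohort_table(table)
    ratio = t["soft_movement"] / t["bone_advancement"]
    rows = {}
    for label, mask in (("Right", t["side"] == "R"),
                        ("Left", t["side"] == "L"),
                        ("Total", np.ones(len(t), dtype=bool))):
        vals = ratio[mask]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows[label] = {"mean": float(vals.mean()), "sd": sd, "n": int(len(vals))}
    return pd.DataFrame.from_dict(rows, orient="index")


def side_comparison(table: pd.DataFrame, variable: str) -> Tuple[float, float]:
    """Paired t-test of right vs left per-patient values of ``variable``.

    Returns ``(t, p)``; identical sides (zero-variance differences) give
    ``(0.0, 1.0)``.
    """
    t = validate_cohort_table(table)
    wide = t.pivot(index="patient", columns="side", values=variable)
    if "L" not in wide or "R" not in wide or wide.dropna().shape[0] < 2:
        raise ValueError("side comparison needs both sides for >= 2 patients")
    paired = wide.dropna()
    diff = paired["R"] - paired["L"]
    if np.allclose(diff.std(ddof=1), 0.0):
        return 0.0, 1.0
    res = stats.ttest_rel(paired["R"], paired["L"])
    return float(res.statistic), float(res.pvalue)


def _corr_r2(y: np.ndarray, fitted: np.ndarray) -> float:
    if np.std(fitted) < 1e-15 or np.std(y) < 1e-15:
        return 0.0
    r = np.corrcoef(y, fitted)[0, 1]
    return float(r * r)


def fit_prediction_model(table: pd.DataFrame, region: str = "Total",
                         include_intercept: bool = False,
                         include_interaction: bool = False) -> PredictionModel:
    """Least-squares fit of Y on (X1, X2), zero-intercept by default.

    ``region`` selects records: "Right"/"Left" restrict by side, anything
    else pools both sides.  Partial R² for each predictor is
    ``(SSE_reduced − SSE_full) / SSE_reduced`` with the other predictor
    retained in the reduced model.  An optional X1·X2 interaction is fitted
    only to report its p-value; coefficients always come from the two-term
    model.
    """
    t = validate_cohort_table(table)
    if region in ("Right", "R"):
        t = t[t["side"] == "R"]
    elif region in ("Left", "L"):
        t = t[t["side"] == "L"]
    if len(t) < 10:
        raise ValueError(f"too few records for regression: {len(t)}")
    y = t["soft_movement"].to_numpy(float)
    X = t[["bone_advancement", "rotation"]].to_numpy(float)
    norms = np.linalg.norm(X, axis=0)
    # a (near-)zero predictor keeps a zero coefficient instead of letting
    # numerical noise produce an arbitrary one
    keep = norms > 1e-8 * max(norms.max(), 1.0)
    if keep.all() and np.linalg.cond(X / norms) > 1e8:
        raise ValueError("advancement and rotation are collinear")
    kept_idx = np.nonzero(keep)[0]
    Xk = X[:, kept_idx]

    def design(M):
        return sm.add_constant(M) if include_intercept else M

    full = sm.OLS(y, design(Xk)).fit()
    slopes = full.params[1:] if include_intercept else full.params
    slope_p = full.pvalues[1:] if include_intercept else full.pvalues
    coefs = np.zeros(2)
    pvals = np.ones(2)
    coefs[kept_idx] = slopes
    pvals[kept_idx] = slope_p
    intercept = float(full.params[0]) if include_intercept else 0.0
    sse_full = float(np.sum(full.resid ** 2))
    partial = [0.0, 0.0]
    for j in kept_idx:
        other = [k for k in kept_idx if k != j]
        if other:
            reduced = sm.OLS(y, design(X[:, other])).fit()
            sse_red = float(np.sum(reduced.resid ** 2))
        else:
            sse_red = float(np.sum((y - (y.mean() if include_intercept
                                         else 0.0)) ** 2))
        partial[j] = (0.0 if sse_red <= 0 else
                      max(0.0, (sse_red - sse_full) / sse_red))
    interaction_p = None
    if include_interaction:
        Xi = np.column_stack([Xk, X[:, 0] * X[:, 1]])
        inter = sm.OLS(y, design(Xi)).fit()
        interaction_p = float(inter.pvalues[-1])
    return PredictionModel(
        region=region, b1=float(coefs[0]), b2=float(coefs[1]),
        intercept=intercept, r_squared=_corr_r2(y, full.fittedvalues),
        partial_r_squared=(partial[0], partial[1]),
        p_values=(float(pvals[0]), float(pvals[1])),
        interaction_p=interaction_p, n=len(t))


def multiple_correlation(model: PredictionModel) -> float:
    """Multiple correlation r = sqrt(R²) = corr(Y, fitted Y)."""
    return float(np.sqrt(model.r_squared))


def norm_comparison(table: pd.DataFrame, stratum: str,
                    norm_mean: float = NORM_MEAN_MM,
                    norm_sd: float = NORM_SD_MM,
                    norm_n: int = NORM_N) -> NormComparison:
    """Welch t-test of one stratum's cheek mass position vs the norm."""
    t = validate_cohort_table(table)
    vals = t.loc[t["stratum"] == stratum, "cheek_mass_position"].to_numpy(float)
    if len(vals) < 2:
        raise ValueError(f"stratum {stratum!r} has fewer than 2 records")
    return norm_comparison_from_summary(
        stratum, float(vals.mean()), float(vals.std(ddof=1)), len(vals),
        norm_mean, norm_sd, norm_n)


def norm_comparison_from_summary(stratum: str, group_mean: float,
                                 group_sd: float, group_n: int,
                                 norm_mean: float = NORM_MEAN_MM,
                                 norm_sd: float = NORM_SD_MM,
                                 norm_n: int = NORM_N) -> NormComparison:
    """Welch comparison straight from summary statistics."""
    tstat, p = stats.ttest_ind_from_stats(
        group_mean, group_sd, group_n, norm_mean, norm_sd, norm_n,
        equal_var=False)
    return NormComparison(
        stratum=stratum, group_mean=group_mean, group_sd=group_sd,
        group_n=group_n, norm_mean=norm_mean, norm_sd=norm_sd, norm_n=norm_n,
        difference=group_mean - norm_mean,
        t_statistic=float(tstat), p_value=float(p))


def norm_comparison_table(table: pd.DataFrame, **norm_kwargs) -> pd.DataFrame:
    """All four strata against the norm, in stratum order."""
    rows = []
    for s in STRATUM_LABELS:
        if (table["stratum"] == s).sum() >= 2:
            c = norm_comparison(table, s, **norm_kwargs)
            rows.append({"stratum": s, "group_mean": c.group_mean,
                         "group_sd": c.group_sd, "n": c.group_n,
                         "norm_mean": c.norm_mean, "norm_sd": c.norm_sd,
                         "difference": c.difference, "t": c.t_statistic,
                         "p": c.p_value})
    return pd.DataFrame(rows)


def icc_absolute_agreement(ratings: np.ndarray) -> float:
    """Single-measure two-way random absolute-agreement ICC — ICC(2,1).

    ``ratings``: raters × targets.  Mean-squares decomposition of the
    two-way layout: with n targets, k raters,

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    where MSR is the between-target, MSC the between-rater and MSE the
    residual mean square.
    """
    R = np.asarray(ratings, float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2D raters x targets array")
    k, n = R.shape
    if k < 2 or n < 5:
        raise ValueError("need >= 2 raters and >= 5 targets")
    if not np.all(np.isfinite(R)):
        raise ValueError("ratings contain missing cells")
    grand = R.mean()
    rater_means = R.mean(axis=1)
    target_means = R.mean(axis=0)
    ss_raters = n * np.sum((rater_means - grand) ** 2)
    ss_targets = k * np.sum((target_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_raters - ss_targets
    msr = ss_targets / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-15:
        raise ValueError("ICC undefined: ratings have no variance")
    return float((msr - mse) / denom)


def ks_normality(values: np.ndarray) -> Tuple[float, float]:
    """One-sample KS test against N(sample mean, sample SD), asymptotic p."""
    v = np.asarray(values, float)
    if len(v) < 5:
        raise ValueError("need at least 5 values for the KS test")
    sd = v.std(ddof=1)
    if sd < 1e-15:
        raise ValueError("KS normality undefined for zero-variance data")
    res = stats.kstest(v, "norm", args=(v.mean(), sd), method="asymp")
    return float(res.statistic), float(res.pvalue)


#: Pearson |r| strength bins: upper edges and labels; 0.8 falls in "strong".
_STRENGTH_BINS = ((0.3, "weak"), (0.6, "moderate"), (0.8, "strong"))


def pearson_strength_label(r: float) -> str:
    """Verbal strength of a Pearson correlation per the |r| cut-offs
    0.3 / 0.6 / 0.8 (boundaries inclusive upward: |r| = 0.3 is moderate,
    |r| = 0.8 is strong)."""
    a = abs(float(r))
    if a > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for edge, label in _STRENGTH_BINS:
        if a < edge or (a == edge and edge == 0.8):
            return label
    return "extremely strong"


def descriptive_by_side(table: pd.DataFrame,
                        variables: Tuple[str, ...] = ("soft_movement",
                                                      "bone_advancement",
                                                      "rotation")) -> pd.DataFrame:
    """Mean ± SD per side and pooled for the movement variables."""
    t = validate_cohort_table(table)
    rows = []
    for var in variables:
        row: Dict[str, float] = {"variable": var}
        for label, mask in (("right", t["side"] == "R"),
                            ("left", t["side"] == "L"),
                            ("total", np.ones(len(t), dtype=bool))):
            vals = t.loc[mask, var]
            row[f"{label}_mean"] = float(vals.mean())
            row[f"{label}_sd"] = float(vals.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
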