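"""Cohort statistics: correlations, group comparisons, regressions.

All standard deviations are sample (n-1) estimates. Group comparison uses
Welch's unequal-variance t-test; correlation significance uses the exact
t-distribution transform of Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

AGE_COLUMN = "Age (years)"
FIRMNESS_COLUMN = "Normalized Skin Firmness"
YOUNG_MAX_AGE = 49.0
OLD_MIN_AGE = 58.0


def load_cohort_table() -> pd.DataFrame:
    """The packaged nine-donor cohort table (one row per donor)."""
    with resources.files("dermafiber").joinpath("data/table1_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def normalize_firmness(values: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; errors on a constant vector."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector")
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def formula(self) -> str:
        return (
            "r = sum((x - mean(x)) (y - mean(y))) / "
            "sqrt(sum((x - mean(x))^2) sum((y - mean(y))^2)); "
            "t = r sqrt((n - 2) / (1 - r^2)) ~ t(n - 2)"
        )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.sum(xc * yc) / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p_value=p, n=n)


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def welch_t_test(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Two-sided Welch (unequal variance) t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("both groups have zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    # Welch-Satterthwaite with the variance ratios normalized to [0, 1]
    # before squaring, so tiny variances cannot underflow to 0/0
    ra, rb = (va / na) / se2, (vb / nb) / se2
    df = 1.0 / (ra**2 / (na - 1) + rb**2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return WelchResult(
        t_statistic=float(t),
        p_value=p,
        df=float(df),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=na,
        n_b=nb,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def simple_linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y = a x + b."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two 1-D arrays with at least 2 points")
    xc = x - x.mean()
    sxx = np.sum(xc**2)
    if sxx == 0:
        raise ValueError("x has zero variance")
    slope = float(np.sum(xc * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    syy = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if syy == 0 else float(1.0 - np.sum(resid**2) / syy)
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r2, n=len(x))


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


def summarize_group(values: np.ndarray) -> GroupSummary:
    """Mean +- sample SD plus Tukey box-plot statistics (1.5 IQR whiskers
    clipped to the data range)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 observations")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return GroupSummary(
        n=len(v),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(lo),
        whisker_high=float(hi),
    )


def split_age_groups(
    table: pd.DataFrame, age_column: str = AGE_COLUMN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Younger (age <= 49) and older (age >= 58) donor subsets."""
    young = table[table[age_column] <= YOUNG_MAX_AGE]
    old = table[table[age_column] >= OLD_MIN_AGE]
    return young, old


def cohort_analysis(table: pd.DataFrame | None = None) -> dict:
    """Full statistical read-out of a cohort table.

    Returns per-variable correlations with age and with normalized firmness,
    young/old group summaries and Welch tests for cluster count and mean
    diameter, and firmness regressions on the architectural variables.
    """
    df = table if table is not None else load_cohort_table()
    age = df[AGE_COLUMN].to_numpy(dtype=float)
    firm = df[FIRMNESS_COLUMN].to_numpy(dtype=float)
    variables = [c for c in df.columns if c != AGE_COLUMN]

    out: dict = {
        "n_donors": len(df),
        "age_correlations": {},
        "firmness_correlations": {},
        "firmness_regressions": {},
        # The normalization basis behind the published standardized slopes is
        # undetermined, so regressions are reported both raw and with the
        # predictor min-max normalized, clearly labeled.
        "firmness_regressions_normalized": {},
        "group_comparisons": {},
    }
    for col in variables:
        v = df[col].to_numpy(dtype=float)
        out["age_correlations"][col] = pearson_correlation(age, v)
        if col != FIRMNESS_COLUMN:
            out["firmness_correlations"][col] = pearson_correlation(v, firm)
            out["firmness_regressions"][col] = simple_linear_regression(v, firm)
            if v.max() > v.min():
                out["firmness_regressions_normalized"][col] = (
                    simple_linear_regression(normalize_firmness(v), firm)
                )

    young, old = split_age_groups(df)
    for col in ["Number of Fiber Clusters", "Mean Fiber Diameter (um)"]:
        if col in df.columns and len(young) >= 2 and len(old) >= 2:
            a = young[col].to_numpy(dtype=float)
            b = old[col].to_numpy(dtype=float)
            out["group_comparisons"][col] = {
                "welch": welch_t_test(a, b),
                "young": summarize_group(a),
                "old": summarize_group(b),
            }
    return out
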