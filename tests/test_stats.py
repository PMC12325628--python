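"""Statistics module: oracle agreement, calibration, and edge cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dermafiber.stats import (
    AGE_COLUMN,
    FIRMNESS_COLUMN,
    cohort_analysis,
    load_cohort_table,
    normalize_firmness,
    pearson_correlation,
    simple_linear_regression,
    split_age_groups,
    summarize_group,
    welch_t_test,
)

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(finite_floats, min_size=3, max_size=30),
    st.integers(min_value=0, max_value=10_000),
)
def test_pearson_matches_scipy(xs, seed):
    x = np.asarray(xs)
    rng = np.random.default_rng(seed)
    y = rng.normal(size=len(x))
    if np.var(x) == 0 or np.var(y) == 0:
        with pytest.raises(ValueError):
            pearson_correlation(x, y)
        return
    ours = pearson_correlation(x, y)
    ref = sps.pearsonr(x, y)
    assert ours.r == pytest.approx(ref.statistic, abs=1e-10)
    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(finite_floats, min_size=2, max_size=20),
    st.lists(finite_floats, min_size=2, max_size=20),
)
def test_welch_matches_scipy(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b) == 0:
        with pytest.raises(ValueError):
            welch_t_test(a, b)
        return
    ours = welch_t_test(a, b)
    ref = sps.ttest_ind(a, b, equal_var=False)
    assert ours.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_regression_matches_brute_force():
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 10, 25)
    y = 3.0 * x - 1.5 + rng.normal(0, 0.5, 25)
    res = simple_linear_regression(x, y)
    # normal-equation oracle
    A = np.stack([x, np.ones_like(x)], axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    assert res.slope == pytest.approx(coef[0], abs=1e-10)
    assert res.intercept == pytest.approx(coef[1], abs=1e-10)
    r = sps.pearsonr(x, y).statistic
    assert res.r_squared == pytest.approx(r**2, abs=1e-10)
    assert np.allclose(res.predict(x), res.slope * x + res.intercept)


def test_welch_null_calibration():
    """Under the null (both groups standard normal) the 5% rejection rate
    should be about 5% over many replicates."""
    rng = np.random.default_rng(2024)
    n_rep = 10_000
    a = rng.normal(size=(n_rep, 8))
    b = rng.normal(size=(n_rep, 12))
    # vectorized Welch identical to welch_t_test
    va, vb = a.var(ddof=1, axis=1), b.var(ddof=1, axis=1)
    se2 = va / 8 + vb / 12
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / ((va / 8) ** 2 / 7 + (vb / 12) ** 2 / 11)
    p = 2.0 * sps.t.sf(np.abs(t), df=df)
    rate = np.mean(p < 0.05)
    assert abs(rate - 0.05) <= 0.01
    # spot-check that the vectorized form matches welch_t_test row by row
    for i in range(5):
        w = welch_t_test(a[i], b[i])
        assert w.p_value == pytest.approx(p[i], abs=1e-12)


def test_normalize_firmness():
    v = np.array([2.0, 4.0, 10.0])
    out = normalize_firmness(v)
    assert out.min() == 0.0 and out.max() == 1.0
    assert out[1] == pytest.approx(0.25)
    with pytest.raises(ValueError):
        normalize_firmness(np.array([3.0, 3.0, 3.0]))


def test_group_summary_order_invariants():
    rng = np.random.default_rng(5)
    v = rng.normal(10, 3, 40)
    s = summarize_group(v)
    assert s.whisker_low <= s.q1 <= s.median <= s.q3 <= s.whisker_high
    assert v.min() <= s.whisker_low and s.whisker_high <= v.max()
    assert s.n == 40


def test_split_age_groups_boundaries():
    df = pd.DataFrame({AGE_COLUMN: [49, 50, 57, 58], "v": [1, 2, 3, 4]})
    young, old = split_age_groups(df)
    assert young[AGE_COLUMN].tolist() == [49]
    assert old[AGE_COLUMN].tolist() == [58]


def test_cohort_analysis_structure():
    out = cohort_analysis()
    assert out["n_donors"] == 9
    # age correlations exist for every non-age column
    df = load_cohort_table()
    assert set(out["age_correlations"]) == set(df.columns) - {AGE_COLUMN}
    assert FIRMNESS_COLUMN not in out["firmness_correlations"]
    # both group comparisons present with Welch + box summaries
    comps = out["group_comparisons"]
    assert set(comps) == {"Number of Fiber Clusters", "Mean Fiber Diameter (um)"}
    for c in comps.values():
        assert c["welch"].n_a == 4 and c["welch"].n_b == 5
    # firmness decreases with age in this cohort
    assert out["age_correlations"][FIRMNESS_COLUMN].r < 0
    # normalized regressions cover the same predictors
    assert set(out["firmness_regressions_normalized"]) == set(
        out["firmness_regressions"]
    )
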