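"""Exact tests, rank test and logistic odds ratios against independent oracles."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from mdopac.stats import (
    CapacityError,
    SeparationError,
    Z_WALD,
    count_tables_with_margins,
    crosstab,
    fisher_exact_2x2,
    format_report,
    format_value,
    freeman_halton,
    logistic_or,
    mann_whitney,
)

# contingency counts of posture category by study group, as published:
# gender x wrist, education level x hip, education level x wrist
GENDER_WRIST = [[19, 17], [8, 31]]
LEVEL_HIP = [[2, 16], [10, 9], [5, 13], [3, 17]]
LEVEL_WRIST = [[9, 9], [12, 7], [2, 16], [4, 16]]


# ---------------------------------------------------------------------------
# Fisher 2x2

@pytest.mark.parametrize(
    "table",
    [GENDER_WRIST, [[5, 5], [5, 5]], [[1, 9], [7, 3]], [[12, 2], [3, 9]], [[2, 0], [3, 5]]],
)
def test_fisher_2x2_matches_scipy_oracle(table):
    ours = fisher_exact_2x2(table)
    oracle = scipy.stats.fisher_exact(table)[1]
    assert ours.p_value == pytest.approx(oracle, abs=1e-12)


def test_fisher_balanced_table_p_one():
    assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0


def test_fisher_extreme_table_closed_form():
    """For a diagonal table only the two extreme tables are as improbable:
    p = 2 / C(20, 10)."""
    res = fisher_exact_2x2([[10, 0], [0, 10]])
    assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)


def test_fisher_enumeration_count_closed_form():
    res = fisher_exact_2x2(GENDER_WRIST)
    # fiber size for a 2x2 table: min(r1, c1) - max(0, r1 - c2) + 1
    assert res.tables_enumerated == min(36, 27) - max(0, 36 - 48) + 1


def test_fisher_zero_margin_warns_p_one():
    assert fisher_exact_2x2([[0, 0], [3, 5]]).p_value == 1.0


# ---------------------------------------------------------------------------
# Freeman-Halton

def test_freeman_halton_level_hip_matches_r_oracle():
    """4x2 hip-by-level exact p; frozen value 0.022326 from R fisher.test."""
    res = freeman_halton(LEVEL_HIP)
    assert res.p_value == pytest.approx(0.0223259, abs=1e-6)


def test_freeman_halton_level_wrist_matches_r_oracle():
    """Frozen from R fisher.test: p = 0.001858."""
    res = freeman_halton(LEVEL_WRIST)
    assert res.p_value == pytest.approx(0.0018581, abs=1e-6)


@pytest.mark.parametrize("table", [GENDER_WRIST, [[3, 7], [6, 2]], [[1, 1], [1, 1]]])
def test_freeman_halton_reduces_to_fisher_on_2x2(table):
    assert freeman_halton(table).p_value == pytest.approx(
        fisher_exact_2x2(table).p_value, abs=1e-12
    )


def test_freeman_halton_enumeration_is_complete():
    """Enumerated table count equals the closed-form fiber size and the
    probabilities over the fiber sum to 1 (checked internally to 1e-9)."""
    res = freeman_halton(LEVEL_HIP)
    t = np.asarray(LEVEL_HIP)
    assert res.tables_enumerated == count_tables_with_margins(
        t.sum(axis=1), t.sum(axis=0)
    )


def test_freeman_halton_capacity_error():
    big = [[100, 100], [100, 100]]
    with pytest.raises(CapacityError):
        freeman_halton(big)


# ---------------------------------------------------------------------------
# Mann-Whitney

def test_mann_whitney_complete_separation():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.U == 0.0
    assert res.mean_rank == (2.0, 5.0)
    assert res.U1 + res.U2 == 9.0


def test_mann_whitney_identical_groups():
    res = mann_whitney([2, 2, 2], [2, 2, 2])
    assert res.p_value == 1.0
    assert res.U == 9 / 2


def test_mann_whitney_u_sum_and_mean_rank_invariants(rng):
    for _ in range(20):
        n1, n2 = rng.integers(2, 12, size=2)
        a = rng.integers(0, 6, size=n1).astype(float)
        b = rng.integers(0, 6, size=n2).astype(float)
        res = mann_whitney(a, b)
        assert res.U1 + res.U2 == pytest.approx(n1 * n2)
        pooled_mean = (res.mean_rank[0] * n1 + res.mean_rank[1] * n2) / (n1 + n2)
        assert pooled_mean == pytest.approx((n1 + n2 + 1) / 2)


def test_mann_whitney_matches_scipy_asymptotic(rng):
    a = rng.normal(0, 1, size=20)
    b = rng.normal(0.5, 1, size=15)
    res = mann_whitney(a, b)
    oracle = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-12)


def test_mann_whitney_exact_agrees_with_brute_force(rng):
    """Exact-mode p equals a direct enumeration over all C(N, n1)
    assignments. The normal approximation can deviate substantially at
    these sizes (exhaustive worst case 0.24 for min group size 2, N <= 10)
    but must stay within that envelope."""
    for trial in range(10):
        n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 6))
        a = rng.normal(0.0, 1.0, size=n1)
        b = rng.normal(0.3, 1.0, size=n2)
        res_ex = mann_whitney(a, b, mode="exact")
        res_as = mann_whitney(a, b, mode="asymptotic")
        # independent brute force on raw values
        pooled = np.concatenate([a, b])
        ranks = scipy.stats.rankdata(pooled)
        mu = n1 * n2 / 2
        obs = abs(res_ex.U1 - mu)
        hits = total = 0
        for subset in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
            total += 1
            hits += abs(u - mu) >= obs - 1e-12
        assert res_ex.p_value == pytest.approx(hits / total, abs=1e-12)
        assert abs(res_as.p_value - res_ex.p_value) < 0.24


# ---------------------------------------------------------------------------
# logistic odds ratios

def _expand(counts, levels):
    """Counts [[acc, comp], ...] per level -> outcome/predictor vectors."""
    y, g = [], []
    for (acc, comp), lv in zip(counts, levels):
        y += [1] * acc + [0] * comp
        g += [lv] * (acc + comp)
    return y, g


@pytest.mark.parametrize(
    "counts,levels,ref",
    [
        (LEVEL_HIP, ["D2", "D3", "D4", "intern"], "intern"),
        (LEVEL_WRIST, ["D2", "D3", "D4", "intern"], "intern"),
        (GENDER_WRIST, ["male", "female"], "male"),
    ],
)
def test_logistic_or_equals_cross_product_ratio(counts, levels, ref):
    """Single-factor logistic is saturated: every Exp(B) must equal the
    2x2 cross-product ratio against the reference level, with Wald SE
    sqrt(1/a + 1/b + 1/c + 1/d), to 1e-6."""
    y, g = _expand(counts, levels)
    results = logistic_or(y, g, ref)
    ref_acc, ref_comp = counts[levels.index(ref)]
    by_term = {r.term: r for r in results}
    for (acc, comp), lv in zip(counts, levels):
        if lv == ref:
            continue
        expected_or = (acc * ref_comp) / (comp * ref_acc)
        se = math.sqrt(1 / acc + 1 / comp + 1 / ref_acc + 1 / ref_comp)
        r = by_term[lv]
        assert r.exp_b == pytest.approx(expected_or, abs=1e-6)
        assert r.se == pytest.approx(se, abs=1e-6)
        assert r.ci_low == pytest.approx(expected_or * math.exp(-Z_WALD * se), rel=1e-5)
        assert r.ci_high == pytest.approx(expected_or * math.exp(Z_WALD * se), rel=1e-5)


def test_logistic_or_matches_statsmodels():
    import statsmodels.api as sm

    y, g = _expand(LEVEL_HIP, ["D2", "D3", "D4", "intern"])
    ours = {r.term: r for r in logistic_or(y, g, "intern")}
    X = np.column_stack(
        [np.ones(len(y))]
        + [(np.array(g) == lv).astype(float) for lv in ("D2", "D3", "D4")]
    )
    fit = sm.GLM(np.array(y), X, family=sm.families.Binomial()).fit()
    # statsmodels' IRLS stops at a looser deviance tolerance than ours
    for j, lv in enumerate(("D2", "D3", "D4"), start=1):
        assert ours[lv].beta == pytest.approx(fit.params[j], rel=1e-4, abs=1e-4)
        assert ours[lv].se == pytest.approx(fit.bse[j], rel=1e-4)


def test_logistic_balanced_table_or_one():
    y, g = _expand([[5, 5], [5, 5]], ["a", "b"])
    (r,) = logistic_or(y, g, "a")
    assert r.exp_b == pytest.approx(1.0, abs=1e-10)


def test_logistic_separation_raises():
    y, g = _expand([[5, 0], [3, 7]], ["a", "b"])
    with pytest.raises(SeparationError):
        logistic_or(y, g, "b")


# ---------------------------------------------------------------------------
# formatting and crosstabs

@pytest.mark.parametrize(
    "x,mode,expected",
    [
        (6.2963, "truncate", "6.29"),
        (6.2963, "round", "6.30"),
        (1.6270, "truncate", "1.62"),
        (0.2309, "truncate", "0.23"),
        (28.8546, "truncate", "28.85"),
    ],
)
def test_format_value_conventions(x, mode, expected):
    assert format_value(x, mode) == expected


def test_p_values_always_round_half_up():
    from mdopac.stats import OddsResult

    r = OddsResult("t", 0.0, 1.0, 1.0, 0.5, 2.0, 0.0076)
    row = format_report([r], round_mode="truncate")[0]
    assert row["p"] == "0.01"
    assert format_value(0.125, "round") == "0.13"


def test_crosstab_counts_and_margins():
    import pandas as pd

    cards = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(4)],
            "wrist_category": ["acceptable", "acceptable", "compromised", "compromised"],
        }
    )
    cov = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(4)],
            "gender": ["male", "female", "male", "female"],
        }
    )
    from mdopac.geometry import ComponentID

    t = crosstab(cards, cov, ComponentID.WRIST, "gender")
    assert t.counts.tolist() == [[1, 1], [1, 1]]
    assert t.row_margins.tolist() == [2, 2]
    assert t.col_margins.tolist() == [2, 2]


def test_crosstab_column_sums_equal_group_sizes(paper_cohort_with_occlusion):
    from mdopac import apply_exclusion_policy, required_landmark_map, score_cohort
    from mdopac.geometry import ComponentID
    from mdopac.scoring import scorecards_to_frame

    kept, _ = apply_exclusion_policy(
        paper_cohort_with_occlusion.captures, required_landmark_map()
    )
    cards, _ = score_cohort(kept)
    df = scorecards_to_frame(cards)
    cov = paper_cohort_with_occlusion.covariates
    t = crosstab(df, cov, ComponentID.HIP_LEVEL, "level")
    sizes = cov[cov.subject_id.isin(df.subject_id)].groupby("level").size()
    for label, margin in zip(t.row_labels, t.row_margins):
        assert margin == sizes[label]


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=2, max_size=4
    )
)
def test_freeman_halton_normalization_property(counts):
    """Fiber probabilities sum to 1 for arbitrary small tables (enforced
    internally to 1e-9; a violation raises)."""
    t = np.array(counts)
    if t.sum() == 0:
        return
    res = freeman_halton(t.tolist())
    assert 0.0 < res.p_value <= 1.0
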