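"""ICC(A,1) against independent oracles; exact nonparametric p-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cravesense.core import ValidationError
from cravesense.reliability import (bonferroni_adjust,
                                    craving_manipulation_check,
                                    feature_reliability, friedman_test,
                                    icc_a1, reliability_report,
                                    wilcoxon_rank_sum, wilcoxon_signed_rank)


def brute_force_icc_a1(table):
    """Independent oracle: explicit sums-of-squares ANOVA, scalar loops."""
    n, k = table.shape
    gm = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(table[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - gm) ** 2 for r in row)
    ssc = n * sum((c - gm) ** 2 for c in col)
    sst = sum((table[i][j] - gm) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def test_icc_is_one_for_identical_columns():
    t = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0], [9.0, 9.0, 9.0]])
    res = icc_a1(t)
    assert res.icc == 1.0
    assert res.p_value == 0.0


def test_icc_matches_bruteforce_on_fixed_table():
    t = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
    assert icc_a1(t).icc == pytest.approx(brute_force_icc_a1(t), abs=1e-12)


def test_icc_matches_pingouin_two_way_absolute_agreement():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    for _ in range(5):
        t = rng.normal(size=(9, 3)) + 1.5 * rng.normal(size=(9, 1))
        long = pd.DataFrame({"t": np.repeat(np.arange(9), 3),
                             "r": np.tile(np.arange(3), 9), "y": t.ravel()})
        ref = pg.intraclass_corr(long, targets="t", raters="r", ratings="y")
        ref = ref[ref.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        mine = icc_a1(t)
        assert mine.icc == pytest.approx(ref.ICC, abs=1e-10)
        assert mine.p_value == pytest.approx(ref.pval, abs=1e-10)


@given(st.integers(0, 1000), st.floats(-50, 50), st.floats(0.1, 20))
def test_icc_invariant_to_shift_and_positive_scale(seed, shift, scale):
    rng = np.random.default_rng(seed)
    t = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
    base = icc_a1(t).icc
    assert icc_a1(t + shift).icc == pytest.approx(base, abs=1e-8)
    assert icc_a1(t * scale).icc == pytest.approx(base, abs=1e-8)


def test_icc_input_validation():
    with pytest.raises(ValidationError):
        icc_a1(np.ones((1, 3)))
    with pytest.raises(ValidationError):
        icc_a1(np.ones((5, 1)))
    bad = np.ones((4, 3)).astype(float)
    bad[0, 0] = np.nan
    with pytest.raises(ValidationError, match="missing"):
        icc_a1(bad)


def test_feature_reliability_table_and_shapes():
    rng = np.random.default_rng(9)
    rows = []
    for subj in ("A", "B", "C", "D"):
        base = rng.normal()
        for sid in ("day1", "day2", "day3"):
            for i in range(6):
                rows.append({"subject_id": subj, "session_id": sid,
                             "trial_index": i,
                             "kind": "wash_off" if i % 2 == 0 else "stimulation",
                             "craving_score": 1,
                             **{f: base + rng.normal() for f in
                                ("stdHR", "mHR", "stdRR", "mRR", "mNSC",
                                 "minNSC", "NE", "DHSM", "DVSM", "mDHV",
                                 "DSM", "CHV", "CHP", "CVP")}})
    table = pd.DataFrame(rows)
    res = feature_reliability(table, "mHR", "wash_off")
    assert -1.0 <= res.icc <= 1.0
    assert res.n == 4 and res.k == 3
    report = reliability_report(table)
    assert len(report) == 14
    assert {"wash_off_icc", "wash_off_p", "stimulation_icc",
            "stimulation_p"} <= set(report.columns)
    # the per-trial-position variant is also available
    res_t = feature_reliability(table, "mHR", "wash_off", unit="trial")
    assert res_t.n == 3  # three wash-off trial slots in this toy table
    one_subject = table[table.subject_id == "A"]
    with pytest.raises(ValidationError):
        feature_reliability(one_subject, "mHR", "wash_off")


def test_rank_sum_exact_and_degenerate_values():
    _, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
    assert p == pytest.approx(0.1)  # most extreme 3-vs-3 ranking
    _, p_same = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p_same >= 0.99


def test_signed_rank_exact_and_degenerate_values():
    _, p = wilcoxon_signed_rank([1, 2, 3], alternative="greater")
    assert p == pytest.approx(1.0 / 8.0)  # all-positive among 2^3 sign patterns
    _, p_anti = wilcoxon_signed_rank([-1.0, 1.0])
    assert p_anti == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="zero"):
        _, p_zero = wilcoxon_signed_rank([2.0, 2.0], [2.0, 2.0])
    assert p_zero == 1.0


def test_friedman_statistic_for_consistent_ordering():
    m = np.array([[1.0, 2.0, 3.0]] * 3)  # identical ranking in every row
    stat, p = friedman_test(m)
    assert stat == pytest.approx(6.0)
    assert p == pytest.approx(stats.chi2.sf(6.0, 2))
    stat0, p0 = friedman_test(np.ones((4, 3)))
    assert (stat0, p0) == (0.0, 1.0)


def test_bonferroni_adjustment():
    assert bonferroni_adjust([0.01], 3)[0] == pytest.approx(0.03)
    assert bonferroni_adjust([0.5], 4)[0] == 1.0
    assert bonferroni_adjust([0.2], 1)[0] == pytest.approx(0.2)
    np.testing.assert_allclose(bonferroni_adjust([0.01, 0.02]), [0.02, 0.04])
    with pytest.raises(ValidationError):
        bonferroni_adjust([1.5], 2)


def test_manipulation_check_on_simulated_study(fast_study):
    check = craving_manipulation_check([fast_study])
    assert len(check) == 1
    row = check.iloc[0]
    assert row.stimulation_median > row.wash_off_median
    assert row.p_value < 0.003
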