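"""Test-retest reliability (ICC) and nonparametric statistics.

The reliability index is ICC(A,1): the single-measurement, absolute-agreement
intraclass correlation from a two-way model, estimated from the ANOVA mean
squares of an n-units x k-sessions table:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the row, column and residual mean squares.  Significance
of H0: ICC <= 0 uses F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.

For the feature-reliability report, the unit of analysis defaults to the
subject: each cell of the table is one subject's mean of a feature over one
session's 18 same-kind trials, giving a 14-features x {wash-off, stimulation}
grid of ICCs — the shape in which per-feature test-retest reliability is
conventionally reported for this paradigm.  A per-trial-position variant
(rows = the 18 trial slots, cells averaged across subjects) is available for
sensitivity analysis.

The two-sample, paired and multi-condition comparisons wrap scipy.stats
(exact Wilcoxon/rank-sum distributions at small n, tie-corrected Friedman),
with Bonferroni adjustment for post-hoc batteries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FEATURE_NAMES, TRIAL_KINDS, SubjectStudy, ValidationError
from .features import FeatureConfig, features_table

__all__ = [
    "ICCResult",
    "icc_a1",
    "feature_reliability",
    "reliability_report",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "friedman_test",
    "bonferroni_adjust",
]


@dataclass
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    f_stat: float
    df1: int
    df2: int
    p_value: float


def icc_a1(table: np.ndarray) -> ICCResult:
    """ICC(A,1) from a complete n x k table (rows = units, cols = sessions)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValidationError("icc_a1 expects a 2-D table")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValidationError(f"icc_a1 needs n >= 2 and k >= 2, got {n}x{k}")
    if not np.all(np.isfinite(table)):
        raise ValidationError("icc_a1: table has missing cells; aggregate first")

    gm = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sst = np.sum((table - gm) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 0.0
    if mse > 0:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:  # zero residual: agreement is exact (or degenerate)
        f = np.inf if msr > 0 else 0.0
        p = 0.0 if msr > 0 else 1.0
    return ICCResult(icc=float(icc), ms_rows=float(msr), ms_cols=float(msc),
                     ms_error=float(mse), n=n, k=k, f_stat=float(f),
                     df1=n - 1, df2=(n - 1) * (k - 1), p_value=p)


def _session_means(table: pd.DataFrame, feature: str, kind: str,
                   unit: str) -> np.ndarray:
    sub = table[table["kind"] == kind]
    if unit == "subject":
        cells = sub.pivot_table(index="subject_id", columns="session_id",
                                values=feature, aggfunc="mean")
    elif unit == "trial":
        cells = sub.pivot_table(index="trial_index", columns="session_id",
                                values=feature, aggfunc="mean")
    else:
        raise ValidationError(f"unknown ICC unit {unit!r}")
    cells = cells.sort_index()
    return cells.to_numpy(dtype=float)


def feature_reliability(studies_or_table, feature: str, kind: str,
                        *, unit: str = "subject",
                        feature_config: FeatureConfig = FeatureConfig(),
                        ) -> ICCResult:
    """ICC(A,1) of one feature for one trial kind across the three sessions.

    ``studies_or_table`` is either a list of :class:`SubjectStudy` (features
    are extracted first) or an already-computed tidy feature table.  With the
    default ``unit="subject"`` the table rows are subjects and each cell is
    that subject's session mean of the feature over the 18 same-kind trials.
    """
    if feature not in FEATURE_NAMES:
        raise ValidationError(f"unknown feature {feature!r}")
    if kind not in TRIAL_KINDS:
        raise ValidationError(f"unknown trial kind {kind!r}")
    table = _coerce_table(studies_or_table, feature_config)
    cells = _session_means(table, feature, kind, unit)
    if cells.shape[0] < 2:
        raise ValidationError("feature_reliability needs at least 2 row units")
    return icc_a1(cells)


def _coerce_table(studies_or_table, feature_config) -> pd.DataFrame:
    if isinstance(studies_or_table, pd.DataFrame):
        return studies_or_table
    studies = studies_or_table
    if isinstance(studies, SubjectStudy):
        studies = [studies]
    return features_table(list(studies), feature_config)


def reliability_report(studies_or_table, *, unit: str = "subject",
                       feature_config: FeatureConfig = FeatureConfig(),
                       ) -> pd.DataFrame:
    """Per-feature ICC and p for wash-off and stimulation trials.

    Returns a 14-row frame with columns ``feature_number, feature,
    wash_off_icc, wash_off_p, stimulation_icc, stimulation_p``.
    """
    table = _coerce_table(studies_or_table, feature_config)
    rows = []
    for num, feature in enumerate(FEATURE_NAMES, start=1):
        row = {"feature_number": num, "feature": feature}
        for kind in TRIAL_KINDS:
            res = feature_reliability(table, feature, kind, unit=unit)
            row[f"{kind}_icc"] = res.icc
            row[f"{kind}_p"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b, *, alternative: str = "two-sided",
                      ) -> tuple[float, float]:
    """Rank-sum (Mann-Whitney) test; exact distribution for small tie-free
    samples, tie-corrected normal approximation otherwise.

    Returns ``(W, p)`` where W is the rank sum of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("wilcoxon_rank_sum: empty sample")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def wilcoxon_signed_rank(a, b=None, *, alternative: str = "two-sided",
                         ) -> tuple[float, float]:
    """Signed-rank test on paired samples (or on ``a`` alone as differences).

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties.  All-zero differences are degenerate evidence of
    no effect: returns ``(0, 1.0)`` with a warning.
    """
    d = np.asarray(a, dtype=float) if b is None else (
        np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("wilcoxon_signed_rank: all differences are zero; p = 1",
                      stacklevel=2)
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (not has_ties and d.size <= 25) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square across the columns of a subjects x conditions
    matrix (tie-corrected ranks, df = c - 1).  Identical columns give
    statistic 0, p = 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 3:
        raise ValidationError("friedman_test needs an n x c matrix with c >= 3")
    if np.all(matrix == matrix[:, [0]]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*[matrix[:, j] for j in range(matrix.shape[1])])
    return float(stat), float(p)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    if m < 1:
        raise ValidationError("bonferroni_adjust: m must be >= 1")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# manipulation check
# ---------------------------------------------------------------------------

def craving_manipulation_check(studies: Sequence[SubjectStudy]) -> pd.DataFrame:
    """Per subject: median (IQR) craving scores by trial kind and the
    rank-sum p-value for stimulation > wash-off pooled over sessions."""
    rows = []
    for study in studies:
        scores = {kind: [] for kind in TRIAL_KINDS}
        for sess in study:
            for tr in sess.trials:
                scores[tr.kind].append(tr.craving_score)
        wash = np.asarray(scores["wash_off"], dtype=float)
        stim = np.asarray(scores["stimulation"], dtype=float)
        _, p = wilcoxon_rank_sum(stim, wash, alternative="greater")
        rows.append({
            "subject_id": study.subject_id,
            "wash_off_median": float(np.median(wash)),
            "wash_off_iqr": float(np.percentile(wash, 75) - np.percentile(wash, 25)),
            "stimulation_median": float(np.median(stim)),
            "stimulation_iqr": float(np.percentile(stim, 75) - np.percentile(stim, 25)),
            "p_value": p,
        })
    return pd.DataFrame(rows)
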