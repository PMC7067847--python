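"""Differential language expression: change, diff-of-diff, and paired tests.

Change is the recent-window minus earlier-window feature value within one
event's lookback; the diff-of-diff subtracts the null event's change from
the true event's change for the same patient.  Per feature, the table of
per-patient diff-of-diffs feeds a two-tailed paired t-test with
Benjamini-Hochberg correction across features, and a paired Cohen's d (d_z:
mean of the paired differences over their standard deviation) with a
normal-approximation 95% confidence interval.

The t statistic, the BH step-up adjustment, and d_z are implemented here
from their definitions; only the t-distribution tail probability comes from
scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureMismatchError",
    "ZeroVarianceError",
    "change",
    "diff_of_diff",
    "change_matrix",
    "diff_of_diff_matrix",
    "paired_t_test",
    "bh_adjust",
    "cohens_d_paired",
    "differential_table",
]


class FeatureMismatchError(ValueError):
    """Two feature vectors do not share the same names in the same order."""


class ZeroVarianceError(ValueError):
    """A paired statistic is undefined because the differences are constant."""


def _check_aligned(a: pd.Series, b: pd.Series) -> None:
    if not a.index.equals(b.index):
        raise FeatureMismatchError("feature names differ between vectors")


def change(recent: pd.Series, earlier: pd.Series) -> pd.Series:
    """Elementwise recent - earlier over identically named features."""
    _check_aligned(recent, earlier)
    return recent - earlier


def diff_of_diff(true_change: pd.Series, null_change: pd.Series) -> pd.Series:
    """Per-feature true-event change minus null-event change."""
    _check_aligned(true_change, null_change)
    return true_change - null_change


def change_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, event) change vectors from a featurized cohort panel.

    ``panel`` is indexed by (patient_id, event, window) as produced by
    :func:`langshift.features.featurize_cohort`.
    """
    recent = panel.xs("recent", level="window")
    earlier = panel.xs("earlier", level="window")
    return recent - earlier


def diff_of_diff_matrix(changes: pd.DataFrame) -> pd.DataFrame:
    """Per-patient diff-of-diff vectors from a change matrix."""
    true_part = changes.xs("true", level="event")
    null_part = changes.xs("null", level="event")
    return true_part - null_part.loc[true_part.index]


def paired_t_test(true_values: Sequence[float],
                  null_values: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on d_i = true_i - null_i, two-tailed.

    Returns (t, p) with p from the t distribution on n-1 degrees of freedom.
    Raises :class:`ZeroVarianceError` when all differences are identical.
    """
    diffs = np.asarray(true_values, dtype=float) - np.asarray(null_values,
                                                              dtype=float)
    n = diffs.size
    if n < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("differences have zero variance")
    t = diffs.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted(i) = min over j with p_(j) >= p_(i) of p_(j)*m/rank(j), capped
    at 1 — i.e. p*m/rank followed by a cumulative minimum from the largest
    rank downwards.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def cohens_d_paired(differences: Sequence[float],
                    variant: str = "dz") -> tuple[float, tuple[float, float]]:
    """Paired-design Cohen's d with a normal-approximation 95% CI.

    The default ``dz`` divides the mean paired difference by the sample
    standard deviation (ddof=1) of the differences.  The CI uses
    SE(d) = sqrt(1/n + d^2/(2n)).
    """
    diffs = np.asarray(differences, dtype=float)
    n = diffs.size
    if n < 3:
        raise ValueError("Cohen's d needs at least 3 pairs")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("differences have zero variance")
    if variant != "dz":
        raise ValueError(f"unknown d variant {variant!r}")
    d = diffs.mean() / sd
    se = np.sqrt(1.0 / n + d ** 2 / (2.0 * n))
    return float(d), (float(d - 1.96 * se), float(d + 1.96 * se))


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature paired statistics of the diff-of-diff analysis."""

    feature: str
    n_pairs: int
    mean_diff_of_diff: float
    t_statistic: float
    p_raw: float
    p_bh: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    mean_ci_low: float
    mean_ci_high: float
    significant: bool
    testable: bool


def differential_table(dod: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """The differential-expression table over all features.

    ``dod`` holds one row per patient, one column per feature (each cell the
    patient's diff-of-diff).  Features whose diff-of-diffs are constant are
    reported as non-testable (NaN statistics) and excluded from the BH
    family.  Rows are ordered increases first, then decreases, by |d|
    descending within each group, non-testable features last.
    """
    if dod.shape[0] < 3:
        raise ValueError("differential analysis needs at least 3 patients")
    n = dod.shape[0]
    records: list[dict] = []
    testable_p: list[float] = []
    for feature in dod.columns:
        diffs = dod[feature].to_numpy(dtype=float)
        mean = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        if sd == 0:
            records.append(dict(
                feature=feature, n_pairs=n, mean_diff_of_diff=mean,
                t_statistic=np.nan, p_raw=np.nan, p_bh=np.nan,
                cohens_d=np.nan, d_ci_low=np.nan, d_ci_high=np.nan,
                mean_ci_low=np.nan, mean_ci_high=np.nan,
                significant=False, testable=False))
            continue
        t, p = paired_t_test(diffs, np.zeros(n))
        d, (d_lo, d_hi) = cohens_d_paired(diffs)
        half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
        records.append(dict(
            feature=feature, n_pairs=n, mean_diff_of_diff=mean,
            t_statistic=t, p_raw=p, p_bh=np.nan, cohens_d=d,
            d_ci_low=d_lo, d_ci_high=d_hi,
            mean_ci_low=mean - half, mean_ci_high=mean + half,
            significant=False, testable=True))
        testable_p.append(p)

    table = pd.DataFrame.from_records(records)
    testable_mask = table["testable"].to_numpy()
    if testable_mask.any():
        adjusted = bh_adjust(np.asarray(testable_p))
        table.loc[testable_mask, "p_bh"] = adjusted
        table.loc[testable_mask, "significant"] = adjusted < alpha

    direction = np.sign(table["cohens_d"].fillna(0.0))
    sort_key = pd.DataFrame({
        "untestable": (~table["testable"]).astype(int),
        "decrease": (direction < 0).astype(int),
        "neg_abs_d": -table["cohens_d"].abs().fillna(-np.inf),
    })
    order = sort_key.sort_values(
        ["untestable", "decrease", "neg_abs_d"], kind="mergesort").index
    return table.loc[order].reset_index(drop=True)
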