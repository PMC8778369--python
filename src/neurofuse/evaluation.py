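"""Accuracy and nonparametric model comparisons.

Classification accuracy is the fraction of correct test predictions times
100.  Paired model comparisons (e.g. transfer-learned EEG vs single-modal
EEG across subjects or seeds) use the two-sided Wilcoxon signed-rank test;
independent group comparisons use the two-sided Mann-Whitney U test.  Both
are computed exactly for the small sample sizes typical of subject-level
tables (n <= 12).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "accuracy",
    "compare_paired",
    "compare_groups",
    "PairedTestResult",
    "GroupTestResult",
]

EXACT_N = 12  # use exact null distributions at or below this sample size


def accuracy(predictions, truth) -> float:
    """Classification accuracy in percent: correct / total x 100."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if predictions.size == 0:
        raise ValueError("cannot compute accuracy of zero samples")
    return float((predictions == truth).mean() * 100.0)


@dataclass
class PairedTestResult:
    """Wilcoxon signed-rank outcome for paired accuracies a vs b."""

    median_difference: float
    p_value: float | None
    statistic: float | None
    n: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < 0.05


@dataclass
class GroupTestResult:
    """Mann-Whitney U outcome for two independent accuracy groups."""

    median_difference: float
    p_value: float
    statistic: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_paired(acc_a, acc_b) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired accuracy vectors.

    Exact for n <= 12.  All-zero differences are reported as degenerate
    (no evidence either way) rather than as NaN.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("paired comparison requires n >= 5")
    d = a - b
    med = float(np.median(d))
    if np.all(d == 0):
        return PairedTestResult(median_difference=0.0, p_value=None,
                                statistic=None, n=len(a), degenerate=True)
    method = "exact" if len(a) <= EXACT_N and not _has_ties_or_zeros(d) else "auto"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return PairedTestResult(median_difference=med, p_value=float(res.pvalue),
                            statistic=float(res.statistic), n=len(a))


def _has_ties_or_zeros(d: np.ndarray) -> bool:
    nz = d[d != 0]
    return (d == 0).any() or len(np.unique(np.abs(nz))) < len(nz)


def compare_groups(acc_group1, acc_group2) -> GroupTestResult:
    """Two-sided Mann-Whitney U test on independent accuracy groups.

    Exact for group sizes <= 12 without ties.
    """
    g1 = np.asarray(acc_group1, dtype=float)
    g2 = np.asarray(acc_group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    method = ("exact" if max(len(g1), len(g2)) <= EXACT_N
              and len(np.unique(np.concatenate([g1, g2]))) == len(g1) + len(g2)
              else "auto")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return GroupTestResult(
        median_difference=float(np.median(g1) - np.median(g2)),
        p_value=float(res.pvalue), statistic=float(res.statistic),
        n1=len(g1), n2=len(g2))
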