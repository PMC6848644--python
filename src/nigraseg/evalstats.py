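"""Segmentation agreement and diagnostic-performance statistics.

Dice similarity with the three-level rating scale (0.00-0.39 low, 0.40-0.79
moderate, 0.80-1.0 high), ROC/AUC with Youden-J optimal cut-offs, the DeLong
test for two correlated ROC curves, Spearman rank correlation with the
five-level strength scale, and the usual two-group tests (Student t,
Mann-Whitney U, chi-squared).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .imageio import LabelMask

__all__ = [
    "DiceReport",
    "ROCReport",
    "DeLongResult",
    "dice",
    "dice_masks",
    "dice_report",
    "rate_dsc",
    "roc_auc",
    "delong_test",
    "spearman_strength",
    "group_compare",
]

POSITIVE_GROUP = "PD"


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) of two boolean regions.

    Symmetric; equals 1 iff the regions are identical, including the
    degenerate both-empty case (agreement on absence).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_masks(
    truth: LabelMask, pred: LabelMask, structure: str, slice_pair: tuple[int, int] | None = None
) -> float:
    """Dice of one structure ('midbrain' or 'snpc') over the evaluation slices.

    The slice pair defaults to the two consecutive slices with the most
    midbrain in the *truth* mask, mirroring how the masks were drawn.
    """
    from .quantify import select_slices

    if truth.shape != pred.shape:
        raise ValueError(f"geometry mismatch: {truth.shape} vs {pred.shape}")
    if slice_pair is None:
        slice_pair = select_slices(truth)
    i, j = slice_pair
    return dice(truth.region(structure)[[i, j]], pred.region(structure)[[i, j]])


def rate_dsc(dsc: float) -> str:
    """Three-level agreement rating: low / moderate / high, band edges as printed."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError(f"dsc must be in [0,1], got {dsc}")
    if dsc < 0.40:
        return "low"
    if dsc < 0.80:
        return "moderate"
    return "high"


@dataclass
class DiceReport:
    structure: str
    values: np.ndarray
    mean: float
    sd: float
    category: str


def dice_report(structure: str, values: Sequence[float]) -> DiceReport:
    values = np.asarray(values, dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("dice values must lie in [0,1]")
    mean = float(values.mean())
    return DiceReport(
        structure=structure,
        values=values,
        mean=mean,
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        category=rate_dsc(mean),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCReport:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    orientation: str
    fpr: np.ndarray
    tpr: np.ndarray


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "low_is_positive":
        return -scores
    if orientation == "high_is_positive":
        return scores
    raise ValueError(f"unknown orientation {orientation!r}")


def _binary_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray([1 if str(l) == POSITIVE_GROUP else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("labels contain a single class")
    return y


def roc_auc(
    scores: Sequence[float], labels: Sequence, orientation: str = "high_is_positive"
) -> ROCReport:
    """ROC analysis of a per-subject statistic against HC/PD labels.

    AUC is computed by the rank (Mann-Whitney) method with ties counting 1/2,
    so it equals U / (n1*n2) exactly.  The optimal cut-off maximizes Youden's
    J = sensitivity + specificity - 1; ties break to higher specificity.  For
    hyperintense areas use ``orientation='low_is_positive'`` (smaller areas
    indicate PD); the reported cut-off is in the original score units, with
    positivity meaning "score <= cutoff" under that orientation.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    s = _oriented(scores, orientation)
    # rank-based AUC: P(S_pos > S_neg) + 0.5 P(S_pos = S_neg)
    ranks = sps.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    fpr, tpr, thr = _sk_roc_curve(y, s)
    j = tpr - fpr
    best = max(range(len(j)), key=lambda i: (j[i], -fpr[i]))
    cut_oriented = thr[best]
    cutoff = -cut_oriented if orientation == "low_is_positive" else cut_oriented
    return ROCReport(
        auc=float(auc),
        cutoff=float(cutoff),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        orientation=orientation,
        fpr=fpr,
        tpr=tpr,
    )


# ---------------------------------------------------------------------------
# DeLong test for two correlated ROC curves
# ---------------------------------------------------------------------------


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong placement values V10 (per positive), V01 (per negative)."""
    x = scores[y == 1]
    yneg = scores[y == 0]
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 otherwise
    psi = (x[:, None] > yneg[None, :]).astype(float) + 0.5 * (x[:, None] == yneg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(v10.mean()), v10, v01


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    orientation: str = "high_is_positive",
) -> DeLongResult:
    """DeLong comparison of two correlated AUCs measured on the same subjects.

    Uses placement values: the variance of ``auc_a - auc_b`` combines the
    empirical covariance of the per-positive placements (divided by the number
    of positives) and of the per-negative placements (divided by the number of
    negatives); z is the standardized difference with a two-sided normal p.
    """
    a = _oriented(np.asarray(scores_a, dtype=float), orientation)
    b = _oriented(np.asarray(scores_b, dtype=float), orientation)
    if a.shape != b.shape:
        raise ValueError("scores_a and scores_b must be paired (same subjects)")
    y = _binary_labels(labels)
    auc_a, v10_a, v01_a = _placements(a, y)
    auc_b, v10_b, v01_b = _placements(b, y)
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 subjects per class")
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return DeLongResult(auc_a, auc_b, 0.0, 1.0)
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(float(auc_a), float(auc_b), float(z), float(p))


# ---------------------------------------------------------------------------
# correlation and group tests
# ---------------------------------------------------------------------------

_SPEARMAN_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.0 + 1e-12, "very strong"),
)


def spearman_strength(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Spearman rank correlation with the five-level strength rating of |r|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r, p = sps.spearmanr(x, y)
    for upper, name in _SPEARMAN_BANDS:
        if abs(r) < upper:
            return float(r), float(p), name
    return float(r), float(p), "very strong"


def group_compare(values_a, values_b=None, test: str = "t") -> tuple[float, float]:
    """Two-group comparison: Student's t (equal variances), Mann-Whitney U, or
    chi-squared on a 2x2 count table (``values_a``, no continuity correction).

    Returns (statistic, two-sided p).
    """
    if test == "chi2":
        table = np.asarray(values_a, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("chi2 expects a 2x2 count table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("chi2 table has a zero margin")
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=True)  # classic Student's t
    elif test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
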