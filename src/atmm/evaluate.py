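"""Evaluation harness: log-CPM, DE ranking statistics, BH, ROC/AUC, FDR.

The ranking statistic is deliberately simple (Welch t for two groups, a
heteroscedastic one-way F for three or more): it is order-sensitive to the
normalization factors through the log-CPM means, which is all that the
ROC/AUC comparison of normalizers requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from atmm.core import CountMatrix

__all__ = ["RocResult", "log_cpm", "de_scores", "bh_adjust", "roc_auc", "empirical_fdr"]

_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class RocResult:
    """ROC curve points (FPR, TPR) from (0,0) to (1,1) and the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def log_cpm(counts: CountMatrix | np.ndarray, effective_library_sizes) -> np.ndarray:
    """log2 counts-per-million on normalized library sizes.

    Computes ``log2((count + 0.5) / (effective_size + 1) * 1e6)``; the
    half-count offset keeps zero counts finite.
    """
    raw = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    sizes = np.asarray(effective_library_sizes, dtype=np.float64)
    if sizes.ndim != 1 or len(sizes) != raw.shape[1]:
        raise ValueError(
            f"effective_library_sizes has length {sizes.size} "
            f"for {raw.shape[1]} samples"
        )
    if np.any(sizes <= 0):
        raise ValueError("effective library sizes must be positive")
    return np.log2((raw + 0.5) / (sizes + 1.0) * 1e6)


def _group_moments(logcpm: np.ndarray, group_of_sample: np.ndarray):
    groups = np.unique(group_of_sample)
    ns, means, variances = [], [], []
    for grp in groups:
        cols = logcpm[:, group_of_sample == grp]
        if cols.shape[1] < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 replicates")
        ns.append(cols.shape[1])
        means.append(cols.mean(axis=1))
        variances.append(np.maximum(cols.var(axis=1, ddof=1), _VAR_FLOOR))
    return np.array(ns), np.column_stack(means), np.column_stack(variances)


def de_scores(logcpm: np.ndarray, group_of_sample) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene DE ranking score (larger = more DE) and two-sided p-value.

    Two groups: absolute Welch (unequal-variance) t statistic with
    Welch-Satterthwaite degrees of freedom. Three or more groups: Welch's
    heteroscedastic one-way F statistic. Within-group variances are floored
    at 1e-8 so zero-variance genes still get finite scores.
    """
    logcpm = np.asarray(logcpm, dtype=np.float64)
    group_of_sample = np.asarray(group_of_sample)
    if len(group_of_sample) != logcpm.shape[1]:
        raise ValueError("group labels do not match the number of samples")
    ns, means, variances = _group_moments(logcpm, group_of_sample)
    k = len(ns)
    if k < 2:
        raise ValueError("need at least 2 groups")

    if k == 2:
        se2 = variances[:, 0] / ns[0] + variances[:, 1] / ns[1]
        t = (means[:, 0] - means[:, 1]) / np.sqrt(se2)
        df = se2 ** 2 / (
            (variances[:, 0] / ns[0]) ** 2 / (ns[0] - 1)
            + (variances[:, 1] / ns[1]) ** 2 / (ns[1] - 1)
        )
        score = np.abs(t)
        p = 2.0 * sps.t.sf(score, df)
        return score, p

    # Welch's one-way heteroscedastic ANOVA
    w = ns / variances
    w_sum = w.sum(axis=1)
    grand = (w * means).sum(axis=1) / w_sum
    between = (w * (means - grand[:, None]) ** 2).sum(axis=1) / (k - 1)
    resid = ((1.0 - w / w_sum[:, None]) ** 2 / (ns - 1)).sum(axis=1)
    f = between / (1.0 + 2.0 * (k - 2) / (k ** 2 - 1) * resid)
    df2 = (k ** 2 - 1) / (3.0 * resid)
    p = sps.f.sf(f, k - 1, df2)
    return f, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC for a DE ranking against binary truth labels.

    The AUC equals the tie-corrected Mann-Whitney probability
    ``P(score_pos > score_neg) + 0.5 * P(equal)`` and the trapezoidal area
    of the returned curve.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc)


def empirical_fdr(calls: np.ndarray, labels: np.ndarray) -> float:
    """False positives over total positives called (0 if nothing is called)."""
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels differ in length")
    n_called = int(calls.sum())
    false_pos = int(np.sum(calls & ~labels))
    return false_pos / max(1, n_called)
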