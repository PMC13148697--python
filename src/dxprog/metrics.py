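"""Evaluation metrics and statistics: AUROC/AUPRC, balanced accuracy,
macro/micro AUROC, Youden operating points, fold ensembling, and the DeLong
test for correlated ROC curves.

All metrics are implemented from their definitions (Mann-Whitney midranks,
average-precision summation, placement values) rather than delegated, so the
test suite can verify them against independent brute-force oracles.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy import stats

from dxprog.exceptions import UndefinedMetricError


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC with midranks; ties count 1/2."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: only one class present")
    r = _midranks(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average-precision form of the area under the precision-recall curve.

    Sum over distinct score thresholds (descending) of
    ``(recall_k - recall_{k-1}) * precision_k``.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC undefined: no positives")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each distinct threshold
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def confusion_matrix(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    """Counts grid, rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (t, p), 1)
    return mat


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Unweighted mean of per-class recall; zero-support classes skipped with warning."""
    mat = np.asarray(confusion, dtype=float)
    if mat.size == 0 or mat.sum() == 0:
        raise UndefinedMetricError("balanced accuracy undefined: empty confusion matrix")
    support = mat.sum(axis=1)
    present = support > 0
    if not present.all():
        warnings.warn("classes with zero support skipped in balanced accuracy", stacklevel=2)
    recall = np.diag(mat)[present] / support[present]
    return float(recall.mean())


def per_class_recall(confusion: np.ndarray) -> np.ndarray:
    mat = np.asarray(confusion, dtype=float)
    support = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(support > 0, np.diag(mat) / support, np.nan)


def macro_micro_auroc(diagnosis_scores, grade_labels) -> tuple[float, float]:
    """One-vs-rest macro AUROC (absent classes skipped with warning) and
    pooled micro AUROC over flattened one-hot labels."""
    probs = np.asarray(diagnosis_scores, dtype=float)
    y = np.asarray(grade_labels, dtype=int)
    n_classes = probs.shape[1]
    present = np.unique(y)
    if len(present) < 2:
        raise UndefinedMetricError("macro/micro AUROC undefined: fewer than 2 classes present")
    per_class = []
    for c in range(n_classes):
        if c not in present:
            warnings.warn(f"class {c} absent from labels; skipped in macro AUROC", stacklevel=2)
            continue
        per_class.append(auroc(probs[:, c], (y == c).astype(int)))
    macro = float(np.mean(per_class))
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y)), y] = 1.0
    micro = auroc(probs.ravel(), onehot.ravel().astype(int))
    return macro, micro


# ---------------------------------------------------------------------------
# Operating points
# ---------------------------------------------------------------------------

def youden_threshold(val_scores, val_labels) -> float:
    """Threshold (from the observed scores) maximizing J = sens + spec - 1.

    Decision rule: score >= threshold => positive. Ties resolved toward the
    smallest maximizing threshold.
    """
    y = _check_binary(val_labels)
    s = np.asarray(val_scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError("Youden threshold undefined: single-class validation labels")
    candidates = np.unique(s)  # ascending
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def sens_spec_at_threshold(test_scores, test_labels, threshold: float):
    """(sensitivity, specificity) of the >=-threshold rule; missing class -> nan with warning."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    y = _check_binary(test_labels)
    s = np.asarray(test_scores, dtype=float)
    pred = s >= threshold
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0:
        warnings.warn("no positives in test set; sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = float((pred & (y == 1)).sum() / n_pos)
    if n_neg == 0:
        warnings.warn("no negatives in test set; specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = float((~pred & (y == 0)).sum() / n_neg)
    return sens, spec


# ---------------------------------------------------------------------------
# Fold ensembling
# ---------------------------------------------------------------------------

def ensemble_scores(per_model_scores: list[dict[str, float]]) -> dict[str, float]:
    """Per scan, the arithmetic mean of available model probabilities."""
    if not per_model_scores:
        raise ValueError("no prediction sets to ensemble")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for scores in per_model_scores:
        for scan_id, value in scores.items():
            sums[scan_id] = sums.get(scan_id, 0.0) + value
            counts[scan_id] = counts.get(scan_id, 0) + 1
    return {scan_id: sums[scan_id] / counts[scan_id] for scan_id in sums}


# ---------------------------------------------------------------------------
# DeLong test for two correlated ROC curves
# ---------------------------------------------------------------------------

class DeLongResult(NamedTuple):
    auroc_a: float
    auroc_b: float
    z: float
    p: float
    n: int


def _placements(scores: np.ndarray, y: np.ndarray):
    """Per-observation placement values (structural components) via midranks."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r, neg_r = _midranks(pos), _midranks(neg)
    a = (all_r[:m] - pos_r) / n  # V10: P(neg < pos_i) with ties 1/2
    b = 1.0 - (all_r[m:] - neg_r) / m  # V01
    theta = a.mean()
    return theta, a, b


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired two-sided DeLong test comparing AUROCs of two score vectors on
    the same labeled scans."""
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if len(sa) != len(sb) or len(sa) != len(y):
        raise ValueError("score vectors and labels must share length")
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError("DeLong undefined: single-class labels")
    m = int(y.sum())
    n = len(y) - m
    theta_a, va10, va01 = _placements(sa, y)
    theta_b, vb10, vb01 = _placements(sb, y)
    if m < 2 or n < 2:
        raise UndefinedMetricError("DeLong needs at least 2 observations per class")
    s10 = np.cov(np.stack([va10, vb10]))  # 2x2, ddof=1
    s01 = np.cov(np.stack([va01, vb01]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = theta_a - theta_b
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            warnings.warn("degenerate DeLong variance with equal AUROCs; p = 1", stacklevel=2)
            return DeLongResult(float(theta_a), float(theta_b), 0.0, 1.0, len(y))
        raise UndefinedMetricError("DeLong variance of the AUROC difference is zero")
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(float(theta_a), float(theta_b), float(z), float(p), len(y))
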