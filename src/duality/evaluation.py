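"""Precision-recall / ROC evaluation, cross-validation, and tool comparison.

The area under the precision-recall curve is computed as average precision
(step interpolation), which avoids the optimism of linear interpolation
between PR points; a trapezoidal variant is available for comparison with
tooling that integrates the curve directly. The area under the ROC curve
is the Mann-Whitney rank-sum statistic U/(n1*n0), with ties given half
credit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .models import TrainingExample, fit_lrm, fit_rfm, predict


@dataclass
class EvalCurve:
    """Threshold-indexed evaluation points with area summaries.

    For PR curves each point is (threshold, precision, recall, f1); for ROC
    curves (threshold, fpr, tpr). The optimal threshold maximises F1, with
    ties broken toward the larger threshold (fewer false positives).
    """

    points: list[tuple]
    auprc: Optional[float] = None
    auroc: Optional[float] = None
    optimal_threshold: Optional[float] = None
    optimal_f1: Optional[float] = None


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def pr_curve(scores, labels, interpolation: str = "step") -> EvalCurve:
    """Precision-recall curve over the unique score values as thresholds
    (predict pathogenic iff score >= threshold).

    Average precision sums precision at each threshold weighted by the
    recall increment; ``interpolation="trapezoid"`` integrates the PR curve
    trapezoidally instead.
    """
    scores, labels = _check_binary(scores, labels)
    n_pos = int(labels.sum())
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    thresholds = np.unique(s)[::-1]
    points = []
    ap = 0.0
    prev_recall = 0.0
    prev_precision = 1.0
    best_f1, best_t = -1.0, None
    idx = 0
    tp = fp = 0
    for t in thresholds:
        while idx < len(s) and s[idx] >= t:
            if y[idx] == 1:
                tp += 1
            else:
                fp += 1
            idx += 1
        precision = tp / (tp + fp)
        recall = tp / n_pos
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        points.append((float(t), precision, recall, f1))
        if interpolation == "step":
            ap += (recall - prev_recall) * precision
        elif interpolation == "trapezoid":
            ap += (recall - prev_recall) * (precision + prev_precision) / 2.0
        else:
            raise ValueError(f"unknown interpolation {interpolation!r}")
        prev_recall, prev_precision = recall, precision
        # ties toward the larger threshold: strict > keeps the earlier (larger) one
        if f1 > best_f1:
            best_f1, best_t = f1, float(t)
    return EvalCurve(
        points=points,
        auprc=float(ap),
        optimal_threshold=best_t,
        optimal_f1=float(best_f1),
    )


def roc_curve(scores, labels) -> EvalCurve:
    """ROC curve; the area equals the rank-sum statistic U/(n1*n0)."""
    scores, labels = _check_binary(scores, labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0], alternative="two-sided")
    auroc = float(u.statistic) / (n1 * n0)
    thresholds = np.unique(scores)[::-1]
    points = []
    for t in thresholds:
        pred = scores >= t
        tpr = float((pred & (labels == 1)).sum()) / n1
        fpr = float((pred & (labels == 0)).sum()) / n0
        points.append((float(t), fpr, tpr))
    return EvalCurve(points=points, auroc=auroc)


@dataclass
class CvResult:
    k: int
    per_fold: list[tuple[float, float]]  # (f1, auprc) per fold
    mean_f1: float
    mean_auprc: float
    fold_assignment_seed: int

    def __post_init__(self) -> None:
        if len(self.per_fold) != self.k:
            raise ValueError("per_fold length must equal k")


def _f1_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def cross_validate(
    training: Sequence[TrainingExample],
    model_kind: str,
    k: int,
    seed: int = 0,
    threshold: float = 0.5,
    max_redraws: int = 20,
    **model_kwargs,
) -> CvResult:
    """Unstratified k-fold cross-validation with per-fold F1 (at a fixed
    threshold, 0.5 by default) and average precision, averaged over folds.

    Folds are redrawn (up to ``max_redraws``) if any held-out fold is
    single-class or, for the logistic model, if a held-out gene is absent
    from its training folds. The random-forest folds reuse the model's
    standard hyperparameters.
    """
    n = len(training)
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    labels = np.array([e.label for e in training], dtype=int)
    genes = np.array([e.gene for e in training])
    idx = np.arange(n)
    for attempt in range(max_redraws):
        fold_seed = seed + attempt
        splits = list(KFold(n_splits=k, shuffle=True, random_state=fold_seed).split(idx))
        ok = all(
            len(np.unique(labels[tr])) == 2
            and len(np.unique(labels[te])) == 2
            and set(genes[te]) <= set(genes[tr])
            for tr, te in splits
        )
        if ok:
            break
    else:
        raise ValueError("could not draw folds with both classes in every fold")

    per_fold = []
    for tr, te in splits:
        train_part = [training[i] for i in tr]
        test_part = [training[i] for i in te]
        if model_kind.upper() == "LRM":
            fit = fit_lrm(train_part, **model_kwargs)
        elif model_kind.upper() == "RFM":
            fit = fit_rfm(train_part, seed=fold_seed, **model_kwargs)
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        scores = predict(fit, test_part)
        y = labels[te]
        f1 = _f1_at(scores, y, threshold)
        auprc = pr_curve(scores, y).auprc
        per_fold.append((float(f1), float(auprc)))
    return CvResult(
        k=k,
        per_fold=per_fold,
        mean_f1=float(np.mean([f for f, _ in per_fold])),
        mean_auprc=float(np.mean([a for _, a in per_fold])),
        fold_assignment_seed=fold_seed,
    )


def rank_sum_compare(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney comparison of two score groups.

    Returns (U, p, probability of superiority), where U counts the pairs in
    which a group-a score exceeds a group-b score (ties half) and the
    probability of superiority is U/(n_a*n_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    ps = float(res.statistic) / (len(a) * len(b))
    return float(res.statistic), float(res.pvalue), ps


#: score direction per comparator tool: +1 means higher = more pathogenic
DEFAULT_ORIENTATIONS: dict[str, int] = {
    "sift": -1,  # lower = more damaging
    "polyphen2": 1,
    "revel": 1,
    "cadd": 1,
    "varity": 1,
    "alphamissense": 1,
    "primateai": 1,
    "vest4": 1,
    "mutpred2": 1,
    "lrm": 1,
    "rfm": 1,
}


def compare_tools(
    score_table: pd.DataFrame,
    labels,
    orientations: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Benchmark per-tool score columns against binary labels.

    Missing scores are excluded pairwise per tool (counts reported); each
    column's direction is normalised via the orientation map (SIFT-style
    scores are negated) before evaluation. Returns a frame ranked by AUPRC.
    """
    orient = {k.lower(): v for k, v in (orientations or DEFAULT_ORIENTATIONS).items()}
    labels = np.asarray(labels, dtype=int)
    rows = []
    for tool in score_table.columns:
        key = tool.lower()
        if key not in orient:
            raise ValueError(f"no orientation entry for tool {tool!r}")
        col = pd.to_numeric(score_table[tool], errors="coerce").to_numpy(dtype=float)
        mask = ~np.isnan(col)
        scores = col[mask] * orient[key]
        y = labels[mask]
        rows.append(
            {
                "tool": tool,
                "auprc": pr_curve(scores, y).auprc,
                "auroc": roc_curve(scores, y).auroc,
                "n_used": int(mask.sum()),
                "n_missing": int((~mask).sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values("auprc", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
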