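"""Imbalance-aware evaluation metrics for ordinal and binary forecasts.

The central quantities are the macro-averaged mean absolute error (MAMAE),
which computes the MAE separately per true class and averages with equal
class weights, and balanced accuracy (BAcc), the mean of sensitivity and
specificity.  Both are robust to the heavy class skew typical of
mental-health self-reports, unlike plain MAE and accuracy which reward
majority-class prediction.  A scale-normalized balanced error maps both onto
a common 0-1 scale (0 = perfect) so ordinal and binary models can be
compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORDINAL_RANGE = (0, 3)


def _check(true, pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.size == 0:
        raise ValueError("metrics undefined for empty label vectors")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return t, p


def mae(true, pred) -> float:
    """Plain mean absolute error."""
    t, p = _check(true, pred)
    return float(np.mean(np.abs(p - t)))


def acc(true, pred) -> float:
    """Plain fraction of exact matches."""
    t, p = _check(true, pred)
    return float(np.mean(t == p))


def per_class_mae(true, pred) -> dict[int, float]:
    """MAE restricted to each class present in the true labels."""
    t, p = _check(true, pred)
    out: dict[int, float] = {}
    for c in np.unique(t):
        m = t == c
        out[int(c)] = float(np.mean(np.abs(p[m] - c)))
    return out

def mamae(true, pred) -> float:
    """Macro-averaged MAE: per-true-class MAE averaged with equal weights.

    Classes absent from ``true`` are excluded (macro-metric convention),
    which keeps the statistic defined on slices missing a rare class.
    """
    return float(np.mean(list(per_class_mae(true, pred).values())))


def bacc(true, pred) -> float:
    """Balanced accuracy (TPR + TNR) / 2 for binary labels.

    Raises when a class is absent from ``true``: the corresponding rate is
    undefined.
    """
    t, p = _check(true, pred)
    pos, neg = t == 1, t == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy needs both classes in the true labels")
    tpr = float(np.mean(p[pos] == 1))
    tnr = float(np.mean(p[neg] == 0))
    return (tpr + tnr) / 2.0


def per_class_recall(true, pred) -> dict[int, float]:
    t, p = _check(true, pred)
    return {int(c): float(np.mean(p[t == c] == c)) for c in np.unique(t)}


def scale_normalized_balanced_error(
    true, pred, task: str, label_range: tuple[int, int] = ORDINAL_RANGE
) -> float:
    """Balanced error on a common 0-1 scale across tasks.

    Binary: ``1 - BAcc``.  Ordinal: the per-class MAE is divided by the
    largest absolute error achievable for that true class,
    ``worst_c = max(c - lo, hi - c)``, then averaged over classes present.
    Both lie in [0, 1]; 0 is a perfect predictor and 1 a maximally wrong one.
    """
    if task == "binary":
        return 1.0 - bacc(true, pred)
    if task != "ordinal":
        raise ValueError(f"unknown task {task!r}")
    lo, hi = label_range
    if lo == hi:
        raise ValueError("degenerate single-point label scale")
    pcm = per_class_mae(true, pred)
    ratios = []
    for c, m in pcm.items():
        worst = max(c - lo, hi - c)
        if worst == 0:
            raise ValueError(f"class {c} has zero worst-case error on this scale")
        ratios.append(m / worst)
    return float(np.mean(ratios))


def confusion_matrix(true, pred, classes) -> np.ndarray:
    """Counts with rows = predicted class, columns = true class."""
    t, p = _check(true, pred)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((k, k), dtype=np.int64)
    for ti, pi in zip(t, p):
        out[idx[int(pi)], idx[int(ti)]] += 1
    return out


@dataclass
class MetricReport:
    """All evaluation numbers for one set of predictions.

    ``bacc`` is None for ordinal predictions (sensitivity/specificity are
    binary notions); ``mamae``/``mae`` are reported for both tasks.
    """

    task: str
    mae: float
    mamae: float
    acc: float
    bacc: float | None
    nbe: float
    per_class_mae: dict = field(default_factory=dict)
    per_class_recall: dict = field(default_factory=dict)
    n_per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "mae": self.mae,
            "mamae": self.mamae,
            "acc": self.acc,
            "bacc": self.bacc,
            "nbe": self.nbe,
            "per_class_mae": self.per_class_mae,
            "per_class_recall": self.per_class_recall,
            "n_per_class": self.n_per_class,
        }


def evaluate(true, pred, task: str) -> MetricReport:
    """Compute the full report for one prediction set."""
    t, _ = _check(true, pred)
    classes, counts = np.unique(t, return_counts=True)
    return MetricReport(
        task=task,
        mae=mae(true, pred),
        mamae=mamae(true, pred),
        acc=acc(true, pred),
        bacc=bacc(true, pred) if task == "binary" else None,
        nbe=scale_normalized_balanced_error(
            true, pred, task, ORDINAL_RANGE if task == "ordinal" else (0, 1)
        ),
        per_class_mae=per_class_mae(true, pred),
        per_class_recall=per_class_recall(true, pred),
        n_per_class={int(c): int(n) for c, n in zip(classes, counts)},
    )


# -- vectorized many-draw versions used by the Monte Carlo baseline ---------

def mamae_draws(true: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """MAMAE of each row of ``draws`` (n_draws x n_test) against ``true``."""
    t = np.asarray(true, dtype=float)
    parts = []
    for c in np.unique(t):
        m = t == c
        parts.append(np.abs(draws[:, m] - c).mean(axis=1))
    return np.mean(parts, axis=0)


def bacc_draws(true: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """BAcc of each row of ``draws`` against binary ``true``."""
    t = np.asarray(true)
    pos, neg = t == 1, t == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy needs both classes in the true labels")
    tpr = (draws[:, pos] == 1).mean(axis=1)
    tnr = (draws[:, neg] == 0).mean(axis=1)
    return (tpr + tnr) / 2.0
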