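"""Monte Carlo baselines, significance calls and cross-condition statistics.

A model's test metric is compared against a baseline distribution built by
repeatedly drawing prediction vectors with replacement from the *training*
labels of the same condition and scoring them against the true test labels
— "best guess" predictions from past self-reports, a harder reference than
chance.  A model is significant when its metric is strictly better than the
baseline quantile at the Bonferroni-corrected alpha (family alpha 0.05 over
the 120 benchmark models, i.e. per-model alpha ~4.2e-4).

1,000 draws cannot resolve a 4.2e-4 quantile, so the default draw count is
12,000; ``n_draws=1000`` reproduces the literal protocol, in which case the
threshold falls back to the extreme order statistic and the call is
annotated as resolution-limited.

Cross-condition comparisons use the Wilcoxon signed-rank test (algorithms),
Friedman tests (horizons, mental states), Spearman rank correlations
(class imbalance vs. performance) and identity-line residuals of the
scale-normalized balanced error (ordinal vs. binary task).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import bacc_draws, mamae_draws

N_BENCHMARK_MODELS = 120
FAMILY_ALPHA = 0.05

_METRIC_DIRECTION = {"mamae": "lower", "bacc": "higher"}
_METRIC_DRAWS = {"mamae": mamae_draws, "bacc": bacc_draws}


@dataclass
class BaselineDistribution:
    condition: dict
    metric: str
    samples: np.ndarray
    n_draws: int
    better_direction: str

    def __post_init__(self) -> None:
        if len(self.samples) != self.n_draws:
            raise ValueError("sample count != n_draws")


@dataclass
class SignificanceCall:
    condition: dict
    metric: str
    model_value: float
    threshold: float
    is_significant: bool
    alpha_corrected: float
    resolution_limited: bool = False


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    table: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def monte_carlo_baseline(
    train_labels,
    test_labels,
    metric: str,
    n_draws: int = 12000,
    seed: int = 0,
    condition: dict | None = None,
) -> BaselineDistribution:
    """Null performance distribution from training-label resampling.

    Each of ``n_draws`` rows samples ``len(test_labels)`` labels with
    replacement from the condition's training labels and is scored against
    the true test labels with ``metric`` ("mamae" or "bacc").
    """
    if metric not in _METRIC_DRAWS:
        raise ValueError(f"unknown baseline metric {metric!r}")
    tr = np.asarray(train_labels)
    te = np.asarray(test_labels)
    if tr.size == 0 or te.size == 0:
        raise ValueError("empty label sets")
    if metric == "bacc" and len(np.unique(te)) < 2:
        raise ValueError("BAcc baseline undefined with single-class test labels")
    rng = np.random.default_rng(seed)
    draws = rng.choice(tr, size=(n_draws, te.size), replace=True)
    samples = _METRIC_DRAWS[metric](te, draws)
    return BaselineDistribution(
        condition=condition or {},
        metric=metric,
        samples=samples,
        n_draws=n_draws,
        better_direction=_METRIC_DIRECTION[metric],
    )


def _ecdf_quantile(sorted_samples: np.ndarray, p: float) -> float:
    """Inverse-ECDF (type 1) quantile of an ascending-sorted sample."""
    n = len(sorted_samples)
    k = int(np.ceil(p * n))
    return float(sorted_samples[max(k, 1) - 1])


def significance_call(
    distribution: BaselineDistribution,
    model_value: float,
    n_models: int = N_BENCHMARK_MODELS,
    family_alpha: float = FAMILY_ALPHA,
) -> SignificanceCall:
    """Is the model strictly better than the Bonferroni-corrected quantile?

    The threshold is the lower-tail quantile of the baseline for
    lower-is-better metrics (MAMAE) and the upper-tail quantile for
    higher-is-better ones (BAcc).  A model exactly at the threshold is not
    significant.
    """
    alpha = family_alpha / n_models
    srt = np.sort(distribution.samples)
    limited = 1.0 / (distribution.n_draws + 1) > alpha
    if distribution.better_direction == "lower":
        thr = srt[0] if limited else _ecdf_quantile(srt, alpha)
        sig = model_value < thr
    else:
        thr = srt[-1] if limited else _ecdf_quantile(srt, 1.0 - alpha)
        sig = model_value > thr
    return SignificanceCall(
        condition=distribution.condition,
        metric=distribution.metric,
        model_value=float(model_value),
        threshold=float(thr),
        is_significant=bool(sig),
        alpha_corrected=alpha,
        resolution_limited=limited,
    )


def compare_algorithms(per_condition: pd.DataFrame, task: str, metric: str) -> ComparisonResult:
    """Wilcoxon signed-rank test of gbt vs rnn over paired conditions.

    ``per_condition`` needs columns item, horizon, algorithm and ``metric``;
    pairs are the (item, horizon) cells within ``task``.  Zero differences
    are dropped (standard treatment); if all differences are zero the test
    degenerates to (statistic 0, p 1).
    """
    sub = per_condition[per_condition["task"] == task]
    wide = sub.pivot_table(index=["item", "horizon"], columns="algorithm", values=metric)
    if wide.isna().any().any() or not {"gbt", "rnn"}.issubset(wide.columns):
        raise ValueError("unpaired or missing conditions for the algorithm comparison")
    d = (wide["gbt"] - wide["rnn"]).to_numpy()
    nz = d[d != 0]
    if nz.size == 0:
        return ComparisonResult("wilcoxon_gbt_vs_rnn", 0.0, 1.0, wide.reset_index())
    method = "exact" if nz.size <= 25 and len(np.unique(np.abs(nz))) == nz.size else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"), method=method)
    return ComparisonResult(
        "wilcoxon_gbt_vs_rnn", float(res.statistic), float(res.pvalue), wide.reset_index()
    )


def friedman_effect(per_condition: pd.DataFrame, factor: str, task: str, metric: str) -> ComparisonResult:
    """Friedman test of a factor ("horizon" or "item") within one task.

    Blocks are the complete crossings of the remaining factors; every block
    must contain each treatment exactly once.  With all treatments
    identical within every block the statistic degenerates to (Q 0, p 1).
    """
    if factor not in ("horizon", "item"):
        raise ValueError("factor must be 'horizon' or 'item'")
    sub = per_condition[per_condition["task"] == task]
    blocks = [c for c in ("item", "horizon", "algorithm") if c != factor]
    wide = sub.pivot_table(index=blocks, columns=factor, values=metric)
    if wide.isna().any().any():
        raise ValueError("incomplete blocks for the Friedman test")
    data = wide.to_numpy()
    if np.allclose(data, data[:, [0]]):
        return ComparisonResult(f"friedman_{factor}", 0.0, 1.0, wide.reset_index())
    res = sps.friedmanchisquare(*[data[:, j] for j in range(data.shape[1])])
    return ComparisonResult(
        f"friedman_{factor}", float(res.statistic), float(res.pvalue), wide.reset_index()
    )


_CORRELATION_PAIRS = {
    "ordinal": [("imbalance", "mamae"), ("imbalance", "mae"), ("mamae", "mae")],
    "binary": [("imbalance", "bacc"), ("imbalance", "acc"), ("bacc", "acc")],
}


def imbalance_correlations(per_condition: pd.DataFrame) -> list[ComparisonResult]:
    """Spearman rank correlations of class imbalance with performance.

    For ordinal conditions: imbalance vs MAMAE and MAE, plus MAMAE vs MAE;
    for binary conditions: imbalance vs BAcc and Acc, plus BAcc vs Acc.
    """
    out = []
    for task, pairs in _CORRELATION_PAIRS.items():
        sub = per_condition[per_condition["task"] == task]
        for a, b in pairs:
            x = sub[a].to_numpy(dtype=float)
            y = sub[b].to_numpy(dtype=float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                raise ValueError(f"constant vector in correlation {a} vs {b}")
            rho, p = sps.spearmanr(x, y)
            out.append(
                ComparisonResult(
                    f"spearman_{task}_{a}_vs_{b}", float(rho), float(p),
                    extra={"task": task, "x": a, "y": b, "n": len(sub)},
                )
            )
    return out


def task_equivalence_residuals(per_condition: pd.DataFrame) -> ComparisonResult:
    """Identity-line residuals of ordinal vs binary scale-normalized error.

    Conditions are matched on (item, algorithm, horizon); the residual is
    nbe_ordinal - nbe_binary.  A mean near 0 indicates the two task
    formulations perform equivalently on the common scale.
    """
    wide = per_condition.pivot_table(
        index=["item", "algorithm", "horizon"], columns="task", values="nbe"
    )
    if wide.isna().any().any() or not {"ordinal", "binary"}.issubset(wide.columns):
        raise ValueError("unmatched ordinal/binary condition pairs")
    resid = (wide["ordinal"] - wide["binary"]).to_numpy()
    table = wide.reset_index().assign(residual=resid)
    return ComparisonResult(
        "task_equivalence_residuals",
        float(np.mean(resid)),
        float("nan"),
        table,
        extra={
            "mean_residual": float(np.mean(resid)),
            "sd_residual": float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0,
        },
    )
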