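"""Shared model scaffolding: configs, ordinal thresholds, prediction sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..metrics import mamae

#: Default thresholds discretizing a continuous prediction into {0,1,2,3}:
#: the midpoints between consecutive ordinal values.
DEFAULT_ORDINAL_THRESHOLDS = (0.5, 1.5, 2.5)


@dataclass(frozen=True)
class OrdinalThresholds:
    """Three strictly increasing cut values on the continuous prediction axis.

    A prediction exactly at a threshold is assigned to the upper class.
    """

    values: tuple = DEFAULT_ORDINAL_THRESHOLDS

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.values)
        if len(v) != 3 or not (v[0] < v[1] < v[2]):
            raise ValueError(f"thresholds must be 3 strictly increasing reals, got {v}")
        object.__setattr__(self, "values", v)

    def discretize(self, continuous) -> np.ndarray:
        return np.searchsorted(np.asarray(self.values), np.asarray(continuous), side="right").astype(np.int64)


@dataclass(frozen=True)
class ModelConfig:
    """One condition of the factorial benchmark plus fitting knobs.

    The recurrent architecture fields default to the benchmark protocol
    (1 LSTM layer, 128 hidden units, 10% dropout, 150 epochs) and only
    change when explicitly overridden, e.g. for scaled-down runs.
    """

    algorithm: str  # "gbt" | "rnn"
    task: str  # "ordinal" | "binary"
    item: str
    horizon: int
    tuning_trials: int = 10
    seed: int = 0
    rnn_layers: int = 1
    rnn_hidden: int = 128
    rnn_dropout: float = 0.10
    rnn_epochs: int = 150
    refit_on_validation: bool = True
    select_best_epoch: bool = True
    fixed_binary_threshold: float | None = None  # None: tuned for validation BAcc

    def __post_init__(self) -> None:
        if self.algorithm not in ("gbt", "rnn"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.task not in ("ordinal", "binary"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.rnn_layers != 1:
            raise ValueError("only the single-layer recurrent architecture is supported")


@dataclass
class PredictionSet:
    """Test-set predictions for one benchmark condition."""

    item: str
    horizon: int
    task: str
    algorithm: str
    participant_ids: list
    dates: list
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray | None = None  # binary P(class 1) or (n, 3) exceedance probs

    def __post_init__(self) -> None:
        if len(self.y_true) != len(self.y_pred):
            raise ValueError("labels and predictions must have equal length")
        admissible = {0, 1, 2, 3} if self.task == "ordinal" else {0, 1}
        if not set(np.unique(self.y_pred)).issubset(admissible):
            raise ValueError(f"predictions outside the {self.task} label space")

    def to_frame(self):
        import pandas as pd

        out = pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "date": self.dates,
                "y_true": self.y_true,
                "y_pred": self.y_pred,
            }
        )
        if self.proba is not None:
            p = np.atleast_2d(self.proba.T).T
            for k in range(p.shape[1]):
                out[f"proba_{k}"] = p[:, k]
        return out


def sample_thresholds(rng: np.random.Generator) -> OrdinalThresholds:
    """One random threshold proposal around the default midpoints.

    Monotonicity is enforced structurally by parameterizing the upper
    thresholds as the first cut plus strictly positive gap increments.
    """
    t1 = rng.normal(0.5, 0.25)
    g1 = abs(rng.normal(1.0, 0.35)) + 0.05
    g2 = abs(rng.normal(1.0, 0.35)) + 0.05
    return OrdinalThresholds((t1, t1 + g1, t1 + g1 + g2))


def tune_thresholds(
    y_val: np.ndarray,
    continuous: np.ndarray,
    n_samples: int = 10,
    seed: int = 0,
    start: tuple = DEFAULT_ORDINAL_THRESHOLDS,
) -> tuple[OrdinalThresholds, float]:
    """Pick the validation-MAMAE-best thresholds among random proposals.

    The candidate set always contains the default midpoints (0.5, 1.5, 2.5)
    plus ``n_samples`` gap-parameterized proposals around them, so the tuned
    validation MAMAE never exceeds the default-threshold MAMAE.  When the
    validation slice carries fewer than 2 distinct classes the defaults are
    returned unchanged (with a warning): the objective cannot rank
    thresholds there.
    """
    y_val = np.asarray(y_val)
    continuous = np.asarray(continuous, dtype=float)
    if len(np.unique(y_val)) < 2:
        warnings.warn(
            "validation slice has <2 classes; falling back to default thresholds"
        )
        t = OrdinalThresholds(start)
        return t, mamae(y_val, t.discretize(continuous))
    rng = np.random.default_rng(seed)
    candidates = [OrdinalThresholds(start)] + [
        sample_thresholds(rng) for _ in range(n_samples)
    ]
    scored = [(mamae(y_val, t.discretize(continuous)), i, t) for i, t in enumerate(candidates)]
    best = min(scored)
    return best[2], best[0]


def tune_binary_threshold(y_val: np.ndarray, proba: np.ndarray) -> tuple[float, float]:
    """Probability cut maximizing validation balanced accuracy.

    Ties favour the smallest threshold; candidates are midpoints between
    consecutive distinct predicted probabilities plus 0.5.
    """
    from ..metrics import bacc

    y_val = np.asarray(y_val)
    p = np.asarray(proba, dtype=float)
    if len(np.unique(y_val)) < 2:
        warnings.warn("single-class validation labels; keeping threshold 0.5")
        return 0.5, float("nan")
    uniq = np.unique(p)
    cands = np.concatenate([[0.5], (uniq[:-1] + uniq[1:]) / 2]) if uniq.size > 1 else np.array([0.5])
    best_t, best_b = 0.5, -np.inf
    for c in np.sort(cands):
        b = bacc(y_val, (p >= c).astype(int))
        if b > best_b + 1e-12:
            best_t, best_b = float(c), float(b)
    return best_t, best_b
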