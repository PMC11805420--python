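"""Time-based splitting, forecast-example construction and standardization.

The split is participant-wise and chronological: the latest 7 surveys of
each participant form the test set, the 7 before those the validation set,
and everything earlier the training set; participants with fewer than 21
surveys are excluded.  Equal per-participant test counts keep evaluation
unbiased by participants who contributed more data.

Each retained survey is paired with 3 days (12 consecutive 6-hour periods)
of sensing input ending ``horizon`` days before the survey date, for
horizons of 0 (same day), 1 (next day) and 7 (next week) days.  Features
are standardized to Gaussian-like distributions with the Yeo-Johnson power
transform fitted on training data only (optionally train+validation for
final model fits), then mean-centred and scaled to unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from sklearn.preprocessing import PowerTransformer

from .cohort import FEATURE_COLUMNS, PERIODS

logger = logging.getLogger(__name__)

HORIZONS = (0, 1, 7)  # days between last input day and the survey
N_PERIODS_PER_EXAMPLE = 12  # 3 days x 4 periods


@dataclass(frozen=True)
class SplitSpec:
    n_test_surveys: int = 7
    n_val_surveys: int = 7
    min_total_surveys: int = 21

    def __post_init__(self) -> None:
        if self.min_total_surveys < self.n_test_surveys + self.n_val_surveys + 1:
            raise ValueError(
                "min_total_surveys must exceed n_test + n_val so every "
                "included participant has at least one training survey"
            )


@dataclass
class SplitAssignment:
    """Per-participant chronological set assignment of survey dates."""

    surveys: pd.DataFrame  # survey table + 'subset' column (train/val/test)
    excluded_participants: list = field(default_factory=list)

    def subset(self, name: str) -> pd.DataFrame:
        return self.surveys[self.surveys["subset"] == name]


@dataclass
class ForecastExample:
    participant_id: str
    survey_date: str
    horizon: int
    x: np.ndarray  # (12, F) chronological period rows
    y: int


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list
    feature_names: tuple
    horizon: int
    item: str
    n_dropped: dict = field(default_factory=dict)  # subset -> dropped surveys
    transform: object = None  # fitted PowerTransformer, if applied
    transform_fitted_on: tuple = ()

    def examples(self, name: str) -> list:
        return {"train": self.train, "validation": self.validation, "test": self.test}[name]


def write_split_manifest(assignment: "SplitAssignment", path) -> None:
    """Participant -> subset -> survey dates, as JSON."""
    import json
    from pathlib import Path

    manifest: dict = {"excluded_participants": list(assignment.excluded_participants)}
    for pid, grp in assignment.surveys.groupby("participant_id"):
        manifest[str(pid)] = {
            subset: sorted(sub["date"].astype(str)) for subset, sub in grp.groupby("subset")
        }
    Path(path).write_text(json.dumps(manifest, indent=2))


def time_split(surveys: pd.DataFrame, spec: SplitSpec = SplitSpec()) -> SplitAssignment:
    """Assign each survey to train/validation/test chronologically."""
    if surveys.duplicated(subset=["participant_id", "date"]).any():
        dup = surveys[surveys.duplicated(subset=["participant_id", "date"])]
        raise ValueError(
            f"duplicate (participant, date) surveys, e.g. {dup.iloc[0].tolist()[:2]}"
        )
    parts, excluded = [], []
    for pid, grp in surveys.groupby("participant_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        n = len(grp)
        if n < spec.min_total_surveys:
            excluded.append(pid)
            continue
        subset = np.array(["train"] * n, dtype=object)
        subset[n - spec.n_test_surveys :] = "test"
        subset[n - spec.n_test_surveys - spec.n_val_surveys : n - spec.n_test_surveys] = "val"
        subset[subset == "val"] = "validation"
        grp["subset"] = subset
        parts.append(grp)
    if not parts:
        raise ValueError("no participant satisfies the minimum-survey requirement")
    return SplitAssignment(
        surveys=pd.concat(parts, ignore_index=True), excluded_participants=excluded
    )


def _day_blocks(sensing: pd.DataFrame) -> dict:
    """participant -> date -> (4, F) period-ordered feature block."""
    order = {p: i for i, p in enumerate(PERIODS)}
    blocks: dict = {}
    feat = sensing[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    pids = sensing["participant_id"].to_numpy()
    dates = sensing["date"].to_numpy()
    pos = sensing["period"].map(order).to_numpy()
    for i in range(len(sensing)):
        day = blocks.setdefault(pids[i], {}).setdefault(
            dates[i], np.full((4, len(FEATURE_COLUMNS)), np.nan)
        )
        day[pos[i]] = feat[i]
    return blocks


def build_examples(
    sensing: pd.DataFrame,
    assignment: SplitAssignment,
    horizon: int,
    item: str,
) -> DatasetSplit:
    """Pair every assigned survey with its 12-period input block.

    For a survey on day d and horizon h, input days are d-h-2 .. d-h; a
    survey whose window is incomplete (any of the 12 periods missing) is
    dropped and counted per subset rather than imputed.
    """
    if horizon not in HORIZONS:
        raise ValueError(f"horizon must be one of {HORIZONS}")
    if item not in assignment.surveys.columns:
        raise KeyError(f"item {item!r} not present in the survey table")
    blocks = _day_blocks(sensing)
    out = {"train": [], "validation": [], "test": []}
    dropped = {"train": 0, "validation": 0, "test": 0}
    pids = assignment.surveys["participant_id"].to_numpy()
    dates = assignment.surveys["date"].to_numpy()
    subsets = assignment.surveys["subset"].to_numpy()
    ys = assignment.surveys[item].to_numpy()
    for pid, date, subset, y in zip(pids, dates, subsets, ys):
        d = pd.Timestamp(date)
        days = [
            (d - pd.Timedelta(days=horizon + k)).strftime("%Y-%m-%d")
            for k in (2, 1, 0)
        ]
        per_day = blocks.get(pid, {})
        mats = [per_day.get(day) for day in days]
        if any(m is None or np.isnan(m).any() for m in mats):
            dropped[subset] += 1
            continue
        out[subset].append(
            ForecastExample(
                participant_id=pid,
                survey_date=str(date),
                horizon=horizon,
                x=np.vstack(mats),
                y=int(y),
            )
        )
    return DatasetSplit(
        train=out["train"],
        validation=out["validation"],
        test=out["test"],
        feature_names=FEATURE_COLUMNS,
        horizon=horizon,
        item=item,
        n_dropped=dropped,
    )


def labels(examples) -> np.ndarray:
    return np.array([e.y for e in examples], dtype=np.int64)


def sequence_tensor(examples) -> np.ndarray:
    """(n, 12, F) float tensor of the input blocks."""
    return np.stack([e.x for e in examples]).astype(float)


def fit_apply_yeo_johnson(
    split: DatasetSplit, include_validation: bool = False
) -> DatasetSplit:
    """Standardize features with a Yeo-Johnson transform fitted on training data.

    Per-feature lambdas are maximum-likelihood estimates on the period rows
    of the training examples pooled across participants (plus validation
    rows when ``include_validation``, used for final model fits); the fitted
    transform and zero-mean/unit-variance scaling are then applied to all
    three subsets.  Near-constant features are left to the transform's
    centring (effectively identity + centering) and logged.
    """
    fit_on = split.train + (split.validation if include_validation else [])
    if not fit_on:
        raise ValueError("no examples to fit the transform on")
    stack = np.vstack([e.x for e in fit_on])
    near_const = np.where(stack.std(axis=0) < 1e-12)[0]
    if near_const.size:
        logger.warning(
            "near-constant features degenerate to identity + centering: %s",
            [split.feature_names[i] for i in near_const],
        )
    pt = PowerTransformer(method="yeo-johnson", standardize=True)
    pt.fit(stack)

    def tx(examples):
        return [dc_replace(e, x=pt.transform(e.x)) for e in examples]

    return DatasetSplit(
        train=tx(split.train),
        validation=tx(split.validation),
        test=tx(split.test),
        feature_names=split.feature_names,
        horizon=split.horizon,
        item=split.item,
        n_dropped=dict(split.n_dropped),
        transform=pt,
        transform_fitted_on=("train", "validation") if include_validation else ("train",),
    )


def tabular_columns(feature_names=FEATURE_COLUMNS) -> list[str]:
    """Deterministic period-indexed column names of the flattened block."""
    return [
        f"{f}_p{p:02d}" for p in range(N_PERIODS_PER_EXAMPLE) for f in feature_names
    ]


def to_tabular(example: ForecastExample) -> np.ndarray:
    """Row-major flattening of the (12, F) block into a 12F vector.

    Entry ``p * F + j`` is feature j in period p, matching
    :func:`tabular_columns`; the inverse mapping is ``vec.reshape(12, F)``.
    """
    return example.x.reshape(-1)


def tabular_matrix(examples) -> np.ndarray:
    return np.stack([to_tabular(e) for e in examples])
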