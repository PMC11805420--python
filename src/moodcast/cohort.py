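"""Synthetic digital-phenotyping cohorts.

Emulates the structure of a smartphone-sensing study in a psychiatric
outpatient population: ~60 participants followed for up to a year, passive
sensing features aggregated over four 6-hour periods per day (night,
morning, afternoon, evening), and tri-weekly (Mon/Wed/Fri) self-report
surveys of 10 mental states rated on a 4-point ordinal scale with heavily
skewed marginals.

The generative model is an ordered probit with a participant random
intercept and an AR(1) daily latent state.  A single "distress" latent
u[p, d] (unit marginal variance) drives

* the ordinal ratings: item latent z = s_j * lambda * u + sqrt(1-lambda^2) * eps
  with s_j = +1 for negative-valence items and -1 for positive ones, cut at
  thresholds chosen by inverse-CDF so realized class proportions match the
  configured marginals exactly in expectation, and

* the sensing features: log-linear (gamma/Poisson) or additive (sleep)
  shifts scaled by ``signal_strength``, so signal_strength = 0 makes labels
  statistically independent of features by construction.

Everything is deterministic given the master seed; per-participant
substreams are spawned from it so generation order does not matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .items import ITEM_NAMES

PERIODS = ("night", "morning", "afternoon", "evening")  # chronological

#: Default target class proportions over ratings {0,1,2,3} per item.
#: Negative rare-event items (Harm, Seeing things, Voices) put 76-81% of mass
#: on "Not at all" and ~3% on "Extremely"; positive items skew high with a
#: 33-48% majority and 7-11% minority; Social is flatter so its best-balanced
#: binary cutoff is the 2-vs-2 split.
DEFAULT_ITEM_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "Calm": (0.10, 0.20, 0.28, 0.42),
    "Hopeful": (0.11, 0.19, 0.27, 0.43),
    "Sleep": (0.09, 0.21, 0.30, 0.40),
    "Social": (0.11, 0.27, 0.32, 0.30),
    "Think": (0.08, 0.20, 0.29, 0.43),
    "Depressed": (0.52, 0.23, 0.15, 0.10),
    "Harm": (0.78, 0.13, 0.06, 0.03),
    "Seeing things": (0.80, 0.11, 0.06, 0.03),
    "Stressed": (0.48, 0.26, 0.16, 0.10),
    "Voices": (0.81, 0.10, 0.06, 0.03),
}

# share of rating-latent variance explained by the distress latent
_ITEM_LOADING = 0.8
# share of distress-latent variance explained by the stable participant trait
_TRAIT_SHARE = 0.5


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 60
    days_per_participant: int | tuple[int, ...] = 365
    survey_weekdays: frozenset = frozenset({0, 2, 4})  # Mon, Wed, Fri
    survey_shift_prob: float = 0.03  # chance a survey lands on an adjacent day
    signal_strength: float = 1.0
    item_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_ITEM_MARGINALS)
    )
    ar_coefficient: float = 0.8
    start_date: str = "2015-03-02"  # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for name, m in self.item_marginals.items():
            m = np.asarray(m, dtype=float)
            if abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"marginals for {name!r} must sum to 1")
            if (m <= 0).any():
                raise ValueError(
                    f"marginals for {name!r} contain a zero-probability class; "
                    "such a class is unreachable with finite cutpoints"
                )

    def participant_days(self) -> list[int]:
        if isinstance(self.days_per_participant, int):
            return [self.days_per_participant] * self.n_participants
        days = list(self.days_per_participant)
        if len(days) != self.n_participants:
            raise ValueError("days_per_participant length != n_participants")
        return days

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "item_marginals" in raw:
            raw["item_marginals"] = {
                k: tuple(v) for k, v in raw["item_marginals"].items()
            }
        if "survey_weekdays" in raw:
            raw["survey_weekdays"] = frozenset(raw["survey_weekdays"])
        if "days_per_participant" in raw and not isinstance(
            raw["days_per_participant"], int
        ):
            raw["days_per_participant"] = tuple(raw["days_per_participant"])
        return cls(**raw)

    def with_(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


def cutpoints_from_marginals(marginals, latent_sd: float = 1.0) -> np.ndarray:
    """Thresholds on a centred Gaussian latent reproducing 4 class proportions.

    Inverse-CDF construction: cut k sits at ``latent_sd * Phi^-1(p_0+...+p_k)``,
    so threshold-crossing probabilities equal the marginals exactly.
    """
    m = np.asarray(marginals, dtype=float)
    if m.shape != (3 + 1,):
        raise ValueError("need exactly 4 class proportions")
    if latent_sd <= 0:
        raise ValueError("latent_sd must be positive")
    if (m <= 0).any():
        raise ValueError("zero-probability class has no finite cutpoint")
    if abs(m.sum() - 1.0) > 1e-9:
        raise ValueError("marginals must sum to 1")
    cuts = latent_sd * norm.ppf(np.cumsum(m)[:3])
    assert np.all(np.diff(cuts) > 0)
    return cuts


# ---------------------------------------------------------------------------
# sensing feature model
# ---------------------------------------------------------------------------

# (name, family, mean, signal loading, weekend log-multiplier,
#  per-period log-multipliers night/morning/afternoon/evening)
# Loadings are on the latent "distress" scale: positive = more of the feature
# when distressed.  Families: gamma (continuous minutes/km), poisson (counts).
_FEATURE_MODEL = [
    ("in_vehicle_min", "gamma", 9.0, -0.10, -0.15, (-2.0, 0.2, 0.3, 0.0)),
    ("on_bike_min", "gamma", 2.0, -0.10, 0.10, (-2.5, 0.1, 0.3, 0.1)),
    ("on_foot_min", "gamma", 18.0, -0.25, 0.05, (-2.0, 0.3, 0.4, 0.0)),
    ("walking_min", "gamma", 14.0, -0.25, 0.05, (-2.0, 0.3, 0.4, 0.0)),
    ("running_min", "gamma", 1.5, -0.15, 0.10, (-2.5, 0.3, 0.2, 0.0)),
    ("still_min", "gamma", 190.0, 0.12, 0.05, (0.5, -0.1, -0.15, 0.0)),
    ("tilting_min", "gamma", 10.0, 0.0, 0.0, (-1.0, 0.1, 0.1, 0.1)),
    ("unknown_min", "gamma", 6.0, 0.0, 0.0, (0.0, 0.0, 0.0, 0.0)),
    ("distance_km", "gamma", 5.0, -0.30, -0.10, (-2.5, 0.3, 0.4, 0.1)),
    ("distinct_locations", "poisson", 1.8, -0.25, -0.10, (-1.5, 0.3, 0.4, 0.1)),
    ("unlock_count", "poisson", 11.0, 0.20, 0.05, (-1.2, 0.2, 0.2, 0.3)),
    ("unlock_duration_min", "gamma", 38.0, 0.20, 0.05, (-1.2, 0.1, 0.2, 0.3)),
    ("call_count", "poisson", 1.4, -0.20, -0.05, (-2.0, 0.2, 0.4, 0.3)),
    ("call_duration_min", "gamma", 4.5, -0.20, -0.05, (-2.0, 0.2, 0.4, 0.3)),
    ("missed_calls", "poisson", 0.4, 0.10, 0.0, (-1.5, 0.1, 0.2, 0.2)),
    ("sms_count", "poisson", 3.0, -0.15, 0.0, (-1.5, 0.2, 0.2, 0.3)),
    ("conversation_count", "poisson", 3.5, -0.30, 0.10, (-2.0, 0.3, 0.4, 0.2)),
    ("conversation_duration_min", "gamma", 28.0, -0.30, 0.10, (-2.0, 0.3, 0.4, 0.2)),
]

_GAMMA_SHAPE = 1.6  # right-skew for all duration/distance features

SLEEP_COLUMNS = ("sleep_start_hr", "sleep_end_hr", "sleep_duration_hr")
CALENDAR_COLUMNS = ("day_of_week", "day_of_month", "is_weekend")

#: Model-input columns of sensing.csv, in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(name for name, *_ in _FEATURE_MODEL) + SLEEP_COLUMNS + CALENDAR_COLUMNS
)

ID_COLUMNS = ("participant_id", "date", "period")


def _participant_frames(
    pid: str,
    n_days: int,
    cfg: CohortConfig,
    cuts: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    dates = pd.date_range(cfg.start_date, periods=n_days, freq="D")
    dow = dates.dayofweek.to_numpy()
    weekend = (dow >= 5).astype(float)

    # latent distress: stable trait + AR(1) daily state, unit marginal variance
    trait = rng.standard_normal()
    phi = cfg.ar_coefficient
    eps = rng.standard_normal(n_days)
    state = np.empty(n_days)
    state[0] = eps[0]
    for d in range(1, n_days):
        state[d] = phi * state[d - 1] + np.sqrt(1 - phi * phi) * eps[d]
    w_t = np.sqrt(_TRAIT_SHARE)
    u = w_t * trait + np.sqrt(1 - _TRAIT_SHARE) * state

    # ---- sensing features ------------------------------------------------
    sig = cfg.signal_strength
    n_rows = n_days * 4
    cols: dict[str, np.ndarray] = {}
    for name, family, mean, beta, wk, per_mult in _FEATURE_MODEL:
        log_m = (
            np.log(mean)
            + np.repeat(sig * beta * u + wk * weekend, 4)
            + np.tile(np.asarray(per_mult), n_days)
        )
        m = np.exp(log_m)
        if family == "gamma":
            cols[name] = rng.gamma(_GAMMA_SHAPE, m / _GAMMA_SHAPE)
        else:
            cols[name] = rng.poisson(m).astype(float)

    sleep_start = 23.5 + 0.3 * sig * u + rng.normal(0, 0.8, n_days)
    sleep_dur = np.clip(7.2 - 0.5 * sig * u + rng.normal(0, 0.9, n_days), 3.0, 12.0)
    sleep_end = (sleep_start + sleep_dur) % 24.0
    sleep_start = sleep_start % 24.0
    cols["sleep_start_hr"] = np.repeat(sleep_start, 4)
    cols["sleep_end_hr"] = np.repeat(sleep_end, 4)
    cols["sleep_duration_hr"] = np.repeat(sleep_dur, 4)

    cols["day_of_week"] = np.repeat(dow, 4).astype(float)
    cols["day_of_month"] = np.repeat(dates.day.to_numpy(), 4).astype(float)
    cols["is_weekend"] = np.repeat(weekend, 4)

    sensing = pd.DataFrame(
        {
            "participant_id": pid,
            "date": np.repeat(dates.strftime("%Y-%m-%d").to_numpy(), 4),
            "period": np.tile(np.asarray(PERIODS, dtype=object), n_days),
            **{c: cols[c] for c in FEATURE_COLUMNS},
        }
    )

    # ---- surveys ---------------------------------------------------------
    scheduled = [d for d in range(n_days) if dow[d] in cfg.survey_weekdays]
    survey_days: list[int] = []
    for d in scheduled:
        if rng.random() < cfg.survey_shift_prob:
            shift = int(rng.choice((-1, 1)))
            d2 = d + shift
            if 0 <= d2 < n_days and d2 not in scheduled and d2 not in survey_days:
                d = d2
        if d not in survey_days:
            survey_days.append(d)
    survey_days.sort()

    ratings = {}
    for name in ITEM_NAMES:
        sign = 1.0 if name in ("Depressed", "Harm", "Seeing things", "Stressed", "Voices") else -1.0
        lam = _ITEM_LOADING
        z = (
            sign * lam * u[survey_days]
            + np.sqrt(1 - lam * lam) * rng.standard_normal(len(survey_days))
        )
        ratings[name] = np.searchsorted(cuts[name], z)
    surveys = pd.DataFrame(
        {
            "participant_id": pid,
            "date": dates[survey_days].strftime("%Y-%m-%d").to_numpy(),
            **ratings,
        }
    )
    return sensing, surveys


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (sensing, surveys) tables for one synthetic cohort.

    Sensing has one row per participant x day x 6-hour period with no missing
    values; surveys one row per participant x survey date with the 10 ordinal
    item ratings as columns.  Byte-identical across runs for a given config.
    """
    cuts = {
        name: cutpoints_from_marginals(m) for name, m in config.item_marginals.items()
    }
    missing = set(ITEM_NAMES) - set(cuts)
    if missing:
        raise ValueError(f"item_marginals missing items: {sorted(missing)}")

    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    sensing_parts, survey_parts = [], []
    for p, (n_days, seq) in enumerate(zip(config.participant_days(), children)):
        pid = f"P{p:03d}"
        s, q = _participant_frames(pid, n_days, config, cuts, np.random.default_rng(seq))
        sensing_parts.append(s)
        survey_parts.append(q)
    return (
        pd.concat(sensing_parts, ignore_index=True),
        pd.concat(survey_parts, ignore_index=True),
    )


def write_cohort(sensing: pd.DataFrame, surveys: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sensing.to_csv(out / "sensing.csv", index=False)
    surveys.to_csv(out / "surveys.csv", index=False)


def read_cohort(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    inp = Path(in_dir)
    return (
        pd.read_csv(inp / "sensing.csv", dtype={"participant_id": str}),
        pd.read_csv(inp / "surveys.csv", dtype={"participant_id": str}),
    )
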