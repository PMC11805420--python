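"""The ten self-reported mental-state items and their binary recoding.

Participants rate each item on a 4-point ordinal scale
(0 = "Not at all", 1 = "A little", 2 = "Moderately", 3 = "Extremely").
Five items have positive valence (a high rating is a good outcome) and five
negative valence (a high rating is a bad outcome).  For the binary
classification task each item is recoded with the cutoff that yields the two
best-balanced classes: 1-vs-3 for nine items, 2-vs-2 for Social, whose
rating distribution is flatter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

RATING_CLASSES = (0, 1, 2, 3)

#: Descriptive constants of the real study cohort this package emulates:
#: number of completed surveys, items per survey, and total rated items.
REFERENCE_N_SURVEYS = 6364
N_ITEMS = 10
REFERENCE_N_RATED_ITEMS = REFERENCE_N_SURVEYS * N_ITEMS


@dataclass(frozen=True)
class MentalStateItem:
    """One survey item with its valence and ordinal-to-binary recoding.

    ``lower_classes`` map to binary 0 ("Lower") and ``higher_classes`` to
    binary 1 ("Higher"), regardless of valence, which fixes the orientation
    of sensitivity/specificity in balanced accuracy.
    """

    name: str
    valence: str  # "positive" | "negative"
    lower_classes: frozenset = field(default_factory=frozenset)
    higher_classes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lower, higher = set(self.lower_classes), set(self.higher_classes)
        if self.valence not in ("positive", "negative"):
            raise ValueError(f"invalid valence {self.valence!r}")
        if lower | higher != set(RATING_CLASSES) or lower & higher:
            raise ValueError("lower/higher classes must partition {0,1,2,3}")
        if not lower or not higher:
            raise ValueError("both class groups must be non-empty")
        # binary recoding of an ordinal scale must cut it at one point
        if max(lower) > min(higher):
            raise ValueError("class groups must be contiguous in the ordinal order")

    @property
    def cutoff(self) -> int:
        """Smallest rating mapped to the Higher class."""
        return min(self.higher_classes)


def default_item_table() -> list[MentalStateItem]:
    """The ten items with their standard binary cutoffs.

    Positive items except Social contrast "Extremely" against the rest;
    negative items contrast "Not at all" against the rest; Social splits
    2-vs-2.
    """

    def item(name: str, valence: str, cut: int) -> MentalStateItem:
        return MentalStateItem(
            name=name,
            valence=valence,
            lower_classes=frozenset(c for c in RATING_CLASSES if c < cut),
            higher_classes=frozenset(c for c in RATING_CLASSES if c >= cut),
        )

    return [
        item("Calm", "positive", 3),
        item("Hopeful", "positive", 3),
        item("Sleep", "positive", 3),
        item("Social", "positive", 2),
        item("Think", "positive", 3),
        item("Depressed", "negative", 1),
        item("Harm", "negative", 1),
        item("Seeing things", "negative", 1),
        item("Stressed", "negative", 1),
        item("Voices", "negative", 1),
    ]


ITEM_NAMES = tuple(it.name for it in default_item_table())


def get_item(name: str) -> MentalStateItem:
    for it in default_item_table():
        if it.name == name:
            return it
    raise KeyError(f"unknown item {name!r}")


def binarize(labels, item: MentalStateItem) -> np.ndarray:
    """Recode ordinal ratings into the item's Lower (0) / Higher (1) classes."""
    arr = np.asarray(labels)
    if arr.size == 0:
        return arr.astype(np.int64)
    if not np.isin(arr, RATING_CLASSES).all():
        raise ValueError("ordinal labels must lie in {0,1,2,3}")
    return (arr >= item.cutoff).astype(np.int64)


def class_imbalance(labels) -> float:
    """(majority count - minority count) / total count, in [0, 1).

    Only classes actually present take part in the majority/minority
    determination, so tiny slices missing a rare class do not saturate the
    statistic.  Applies identically to ordinal and binary label vectors.
    """
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("class imbalance undefined for empty labels")
    counts = np.unique(arr, return_counts=True)[1]
    return float((counts.max() - counts.min()) / arr.size)


def item_table_to_json() -> str:
    return json.dumps(
        [
            {
                "name": it.name,
                "valence": it.valence,
                "lower": sorted(it.lower_classes),
                "higher": sorted(it.higher_classes),
            }
            for it in default_item_table()
        ],
        indent=2,
    )
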