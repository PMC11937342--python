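"""Rating tables, questionnaire scoring, and exclusion rules.

Participants rate how well each of K trait adjectives describes them (self
block), how useful each trait is in their current life (utility block), and —
in the extended design — how much each trait matches the person they would
like to be (ideal) or feel they should be (ought).  All ratings live on a
1-100 slider scale.  Questionnaires are summed Likert scales: a 12-item
self-concept-clarity scale (5-point items) and the 10-item Rosenberg
self-esteem scale (4-point items).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BLOCKS",
    "RatingTable",
    "TraitLexicon",
    "ScaleScore",
    "ExclusionReport",
    "read_rating_table",
    "write_rating_table",
    "score_scale",
    "apply_exclusions",
    "SCC_REVERSE_KEYS",
    "RSES_REVERSE_KEYS",
]

BLOCKS = ("self", "utility", "ideal", "ought", "reference")

RATING_MIN = 1.0
RATING_MAX = 100.0

#: Standard reverse-keyed items (1-based positions) for the published scales.
#: The 12-item Self-Concept Clarity scale reverse-keys all items except 6 and 11;
#: the Rosenberg Self-Esteem scale reverse-keys items 2, 5, 6, 8, 9.
SCC_REVERSE_KEYS = (1, 2, 3, 4, 5, 7, 8, 9, 10, 12)
RSES_REVERSE_KEYS = (2, 5, 6, 8, 9)


class ValidationError(ValueError):
    """Raised when an input table violates the rating-scale contract."""


@dataclass
class RatingTable:
    """Subjects x traits rating matrix for one block.

    Values are floats in [1, 100]; missing cells are NaN.  The table wraps a
    pandas DataFrame indexed by subject id with trait labels as columns.
    """

    data: pd.DataFrame
    block: str

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValidationError(f"unknown block {self.block!r}; expected one of {BLOCKS}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate trait labels: {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        bad = (values < RATING_MIN) | (values > RATING_MAX)
        bad &= ~np.isnan(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"rating out of [1, 100] for subject {self.data.index[i]!r}, "
                f"trait {self.data.columns[j]!r}: {values[i, j]}"
            )
        self.data = self.data.astype(float)
        self.data.index.name = "subject_id"
        self.data.columns.name = None

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def n_missing(self, subject_id) -> int:
        return int(self.data.loc[subject_id].isna().sum())


@dataclass
class TraitLexicon:
    """Trait adjectives with their valence; the study list has 25 of each."""

    labels: list[str]
    valence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("trait labels must be unique")
        for label, v in self.valence.items():
            if v not in ("positive", "negative"):
                raise ValidationError(f"valence for {label!r} must be positive|negative")

    def counts(self) -> dict[str, int]:
        out = {"positive": 0, "negative": 0}
        for v in self.valence.values():
            out[v] += 1
        return out


@dataclass
class ScaleScore:
    subject_id: object
    scale_name: str
    item_responses: np.ndarray
    score: float  # NaN when any item response is missing


@dataclass
class ExclusionReport:
    subject_id: object
    n_missing: int
    n_total: int
    missing_fraction: float
    retained: bool


def read_rating_table(path, block: str) -> RatingTable:
    """Read a wide ratings CSV (col 1 = subject id, remaining cols = traits).

    Empty cells are preserved as missing values.
    """
    df = pd.read_csv(path, index_col=0)
    return RatingTable(df, block)


def write_rating_table(table: RatingTable, path) -> None:
    table.data.to_csv(path, index_label="subject_id")


def score_scale(
    items,
    reverse_keys=(),
    item_min: int = 1,
    item_max: int = 5,
    scale_name: str = "scale",
    subject_ids=None,
) -> list[ScaleScore]:
    """Sum-score a Likert scale with reverse coding.

    Parameters
    ----------
    items : (n_subjects, n_items) array-like
        Integer responses; NaN marks a missing item.
    reverse_keys : iterable of int
        1-based item positions to reverse; reversed response = min + max - x.
    item_min, item_max : int
        Response bounds (e.g. 1..5 for the clarity scale, 1..4 for Rosenberg).

    A subject with any missing item receives a NaN score (no imputation).
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    n, k = arr.shape
    keys = sorted(set(int(r) for r in reverse_keys))
    if any(r < 1 or r > k for r in keys):
        raise ValidationError(f"reverse key out of range 1..{k}: {keys}")
    finite = ~np.isnan(arr)
    if ((arr < item_min) | (arr > item_max))[finite].any():
        raise ValidationError(f"item response outside [{item_min}, {item_max}]")
    coded = arr.copy()
    for r in keys:
        coded[:, r - 1] = item_min + item_max - coded[:, r - 1]
    scores = coded.sum(axis=1)
    scores[np.isnan(coded).any(axis=1)] = np.nan
    if subject_ids is None:
        subject_ids = list(range(n))
    return [
        ScaleScore(sid, scale_name, arr[i], float(scores[i]))
        for i, sid in enumerate(subject_ids)
    ]


def apply_exclusions(responses: dict, threshold: float = 0.20) -> list[ExclusionReport]:
    """Exclude subjects missing strictly more than ``threshold`` of responses.

    ``responses`` maps subject id -> (n_missing, n_total).  The boundary is
    retained: exactly 20% missing does not trigger exclusion.
    """
    reports = []
    for sid, (n_missing, n_total) in responses.items():
        if n_total <= 0:
            raise ValidationError(f"subject {sid!r}: zero expected responses")
        frac = n_missing / n_total
        reports.append(
            ExclusionReport(sid, int(n_missing), int(n_total), frac, frac <= threshold)
        )
    return reports


def exclusion_counts(table: RatingTable) -> dict:
    """Per-subject (n_missing, n_total) pairs for `apply_exclusions`."""
    k = len(table.trait_labels)
    return {sid: (table.n_missing(sid), k) for sid in table.subject_ids}
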