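"""Profile-discrepancy metrics between a self profile and a comparison profile.

Self-utility distance (SUD) is the mean absolute difference between a
subject's self ratings and their utility ratings over the trait list — an
average Manhattan distance, which normalises for missing items.  Ideal- and
ought-self discrepancies use the same operationalisation against ideal/ought
profiles.  A Euclidean variant and a Pearson variant (a *similarity*, sign
reversed relative to distance) are provided for control analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ratings import RatingTable

__all__ = ["DiscrepancyResult", "profile_distance", "discrepancy_table", "METRICS"]

logger = logging.getLogger(__name__)

METRICS = ("manhattan_mean", "euclidean", "pearson")


@dataclass
class DiscrepancyResult:
    subject_id: object
    metric: str
    value: float
    n_pairs_used: int


def profile_distance(s, u, metric: str = "manhattan_mean", subject_id=None) -> DiscrepancyResult:
    """Discrepancy between two equal-length rating vectors.

    Pairs with a missing value on either side are dropped (pairwise deletion).
    manhattan_mean averages |s_k - u_k| over the used pairs; euclidean is the
    root summed squared difference (not normalised); pearson is the sample
    correlation and requires >= 2 pairs with variance on both sides.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    if s.shape != u.shape:
        raise ValueError(f"profile length mismatch: {s.shape} vs {u.shape}")
    mask = ~np.isnan(s) & ~np.isnan(u)
    n = int(mask.sum())
    sv, uv = s[mask], u[mask]
    if metric == "manhattan_mean":
        if n < 1:
            raise ValueError("manhattan_mean needs at least one usable pair")
        value = float(np.mean(np.abs(sv - uv)))
    elif metric == "euclidean":
        if n < 1:
            raise ValueError("euclidean needs at least one usable pair")
        value = float(np.sqrt(np.sum((sv - uv) ** 2)))
    else:  # pearson
        if n < 2:
            raise ValueError("pearson needs at least two usable pairs")
        if np.std(sv) == 0 or np.std(uv) == 0:
            raise ValueError("pearson undefined for a zero-variance profile")
        value = float(np.corrcoef(sv, uv)[0, 1])
    return DiscrepancyResult(subject_id, metric, value, n)


def discrepancy_table(
    self_table: RatingTable, other_table: RatingTable, metric: str = "manhattan_mean"
) -> list[DiscrepancyResult]:
    """Per-subject discrepancies between two aligned rating tables.

    Subjects for whom the metric's preconditions fail (e.g. no usable pairs)
    get a NaN value with a logged reason rather than aborting the cohort.
    """
    if list(self_table.trait_labels) != list(other_table.trait_labels):
        raise ValueError("trait labels differ between the two tables")
    if list(self_table.subject_ids) != list(other_table.subject_ids):
        raise ValueError("subject ids differ between the two tables")
    results = []
    for sid in self_table.subject_ids:
        s = self_table.data.loc[sid].to_numpy(dtype=float)
        u = other_table.data.loc[sid].to_numpy(dtype=float)
        try:
            results.append(profile_distance(s, u, metric, subject_id=sid))
        except ValueError as exc:
            logger.warning("subject %r: %s; value set to missing", sid, exc)
            mask = ~np.isnan(s) & ~np.isnan(u)
            results.append(DiscrepancyResult(sid, metric, float("nan"), int(mask.sum())))
    return results
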