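"""Ordinal agreement between dryness-rating columns.

Mismatch is strict label inequality (no partial credit); severity is the
absolute distance on the ordinal levels dry=0 .. sweet=3, which is how
"different by more than one level" statements are counted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import pandas as pd

from .categories import DrynessCategory

RatingColumn = Union[Mapping[str, object], pd.Series]

#: candidate columns of the validation table, compared against the panel
DEFAULT_CANDIDATES = ("nyca_rating", "model1_rating", "model2_rating", "model3_rating")


@dataclass
class MismatchReport:
    """Pairwise agreement summary between a reference and a candidate column."""

    n_compared: int
    n_mismatch: int
    by_distance: dict         # {1: count, 2: count, 3: count}
    mismatched_ids: list

    @property
    def n_multi_level(self) -> int:
        """Samples rated off by more than one ordinal level."""
        return sum(c for d, c in self.by_distance.items() if d >= 2)


@dataclass
class ComparisonSummary:
    reports: dict                       # candidate name -> MismatchReport
    ranking: list = field(default_factory=list)  # (name, n_mismatch), best first


def _as_category_map(column: RatingColumn) -> dict:
    if isinstance(column, pd.Series):
        items = column.items()
    else:
        items = column.items()
    return {str(k): DrynessCategory.from_label(v) for k, v in items}


def compare_ratings(reference: RatingColumn, candidate: RatingColumn) -> MismatchReport:
    """Count per-sample rating disagreements between two columns.

    Both columns must cover the same sample ids; values may be labels or
    :class:`DrynessCategory`.
    """
    ref = _as_category_map(reference)
    cand = _as_category_map(candidate)
    if set(ref) != set(cand):
        diff = sorted(set(ref) ^ set(cand))
        raise ValueError(f"sample ids differ between columns: {diff}")
    by_distance = {1: 0, 2: 0, 3: 0}
    mismatched = []
    for sid in ref:
        d = abs(int(ref[sid]) - int(cand[sid]))
        if d > 0:
            by_distance[d] += 1
            mismatched.append(sid)
    return MismatchReport(
        n_compared=len(ref),
        n_mismatch=len(mismatched),
        by_distance=by_distance,
        mismatched_ids=sorted(mismatched),
    )


def comparison_table(
    records: pd.DataFrame,
    reference: str = "sensory_rating",
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> ComparisonSummary:
    """One MismatchReport per candidate column against the reference column.

    ``records`` is a validation-style table with a ``sample_id`` column; the
    ranking lists candidates from fewest to most mismatches.
    """
    if len(records) == 0:
        raise ValueError("record set is empty")
    indexed = records.set_index("sample_id")
    ref = indexed[reference]
    reports = {name: compare_ratings(ref, indexed[name]) for name in candidates}
    ranking = sorted(
        ((name, rep.n_mismatch) for name, rep in reports.items()), key=lambda kv: kv[1]
    )
    return ComparisonSummary(reports=reports, ranking=ranking)
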