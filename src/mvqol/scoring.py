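"""WHOQOL-HIV BREF domain scoring and visit/subject inclusion filters.

Each domain score is four times the mean of that domain's 5-point Likert
items, giving the 4-20 range comparable with the WHOQOL-100 scoring
pattern.  Visits whose domains cannot all be scored are flagged
incomplete and removed by :func:`filter_complete_visits`; subjects left
with fewer than two visits are removed by :func:`filter_min_visits`.
The pipeline fixes the order complete-visit filter -> min-visit filter,
since completeness can only reduce a subject's visit count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import COMPLETE_COL, DOMAINS, SUBJECT_COL
from .dataset import CohortDataset
from .exceptions import ValidationError


class _Incomplete:
    """Sentinel for a domain/visit that cannot be scored."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "INCOMPLETE"


INCOMPLETE = _Incomplete()

#: fraction of a domain's items that must be present for it to be scorable
DEFAULT_MIN_COMPLETE = 0.8


@dataclass(frozen=True)
class DomainScores:
    """The four domain scores of one visit, each in [4, 20]."""

    ph: float
    psy: float
    ind: float
    soc: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DOMAINS}


def score_domain(
    items: Sequence[float | None],
    min_complete: float = DEFAULT_MIN_COMPLETE,
):
    """Score one domain: 4 x mean of the present Likert items.

    Missing items may be passed as None or NaN.  Returns the float score
    in [4, 20], or :data:`INCOMPLETE` when fewer than ``min_complete`` of
    the items are present.  Any present item outside {1..5} raises
    :class:`ValidationError`.
    """
    items = list(items)
    if not items:
        raise ValidationError("score_domain requires at least one item")
    present: list[int] = []
    for x in items:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            continue
        xf = float(x)
        if xf != int(xf) or not 1 <= xf <= 5:
            raise ValidationError(f"Likert item {x!r} outside the integer range 1..5")
        present.append(int(xf))
    if len(present) < min_complete * len(items) or not present:
        return INCOMPLETE
    return 4.0 * (sum(present) / len(present))


def score_visit(
    items_by_domain: Mapping[str, Sequence[float | None]],
    min_complete: float = DEFAULT_MIN_COMPLETE,
):
    """Score all four domains of one visit.

    Returns a :class:`DomainScores`, or :data:`INCOMPLETE` if any domain
    cannot be scored.  A mapping with precomputed numeric scores (one
    value per domain) passes through unchanged.
    """
    scores: dict[str, float] = {}
    for k in DOMAINS:
        if k not in items_by_domain:
            return INCOMPLETE
        val = items_by_domain[k]
        if isinstance(val, (int, float)):  # precomputed score passthrough
            if math.isnan(float(val)):
                return INCOMPLETE
            scores[k] = float(val)
            continue
        s = score_domain(val, min_complete=min_complete)
        if s is INCOMPLETE:
            return INCOMPLETE
        scores[k] = s
    return DomainScores(**scores)


def score_dataset(
    dataset: CohortDataset, min_complete: float = DEFAULT_MIN_COMPLETE
) -> CohortDataset:
    """Score every visit of a cohort from its item columns.

    Item columns follow the ``dom{k}_item{i}`` convention with ``k`` the
    1-based domain index in canonical order.  When the four score
    columns are already present the input is returned unchanged apart
    from the completeness flag.
    """
    df = dataset.data.copy()
    item_cols = {
        k: sorted(c for c in df.columns if c.startswith(f"dom{i + 1}_item"))
        for i, k in enumerate(DOMAINS)
    }
    have_items = all(item_cols[k] for k in DOMAINS)
    if not have_items:
        if not dataset.has_scores():
            raise ValidationError(
                "dataset carries neither item columns (dom{k}_item{i}) nor "
                "domain-score columns " + "/".join(DOMAINS)
            )
        if COMPLETE_COL not in df.columns:
            df[COMPLETE_COL] = ~df[list(DOMAINS)].isna().any(axis=1)
        return CohortDataset(df, dataset.schema, dataset.truth)

    for k in DOMAINS:
        vals = df[item_cols[k]].to_numpy(dtype=float)
        scored = np.empty(len(df))
        for i, row in enumerate(vals):
            s = score_domain(row, min_complete=min_complete)
            scored[i] = np.nan if s is INCOMPLETE else s
        df[k] = scored
    df[COMPLETE_COL] = ~df[list(DOMAINS)].isna().any(axis=1)
    return CohortDataset(df, dataset.schema, dataset.truth)


def filter_complete_visits(dataset: CohortDataset):
    """Drop visits with any unscorable domain.

    Returns ``(filtered_dataset, n_dropped, pct_dropped)`` with the
    percentage rounded to one decimal, matching how cohort attrition is
    conventionally reported.
    """
    df = dataset.data
    if len(df) == 0:
        raise ValidationError("cannot filter an empty dataset")
    if COMPLETE_COL in df.columns:
        keep = df[COMPLETE_COL].astype(bool)
    elif dataset.has_scores():
        keep = ~df[list(DOMAINS)].isna().any(axis=1)
    else:
        raise ValidationError("dataset has neither scores nor a completeness flag")
    n_total = len(df)
    n_dropped = int((~keep).sum())
    pct = round(100.0 * n_dropped / n_total, 1)
    out = df.loc[keep].copy()
    return CohortDataset(out, dataset.schema, dataset.truth), n_dropped, pct


def filter_min_visits(dataset: CohortDataset, min_visits: int = 2):
    """Remove subjects with fewer than ``min_visits`` remaining visits.

    Returns ``(filtered_dataset, n_subjects_dropped)``.
    """
    if min_visits < 1:
        raise ValidationError("min_visits must be >= 1")
    counts = dataset.data[SUBJECT_COL].value_counts()
    keep_subjects = counts.index[counts >= min_visits]
    n_dropped = int(len(counts) - len(keep_subjects))
    out = dataset.data[dataset.data[SUBJECT_COL].isin(keep_subjects)].copy()
    return CohortDataset(out, dataset.schema, dataset.truth), n_dropped
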