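"""Cohort data container: long-format visit records plus metadata.

A cohort is a long-format :class:`pandas.DataFrame` (one row per clinic
visit) wrapped together with a covariate schema and, for simulated
cohorts, the generating truth (parameters and per-subject random
effects) needed by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .constants import DOMAINS, SUBJECT_COL, TIME_COL
from .exceptions import ValidationError


@dataclass
class CovariateSchema:
    """Names, types and reference categories of model covariates.

    ``spec`` maps covariate name -> dict with keys ``type``
    ("categorical" | "continuous"), and for categoricals ``levels``
    (ordered, first = reference) .
    """

    spec: dict[str, dict[str, Any]] = field(default_factory=dict)

    def reference(self, name: str) -> Any:
        return self.spec[name]["levels"][0]

    def is_categorical(self, name: str) -> bool:
        return self.spec.get(name, {}).get("type") == "categorical"

    @property
    def names(self) -> list[str]:
        return list(self.spec)


@dataclass
class CohortTruth:
    """Generating parameters stored alongside a simulated cohort."""

    beta: dict[str, dict[str, float]]
    omega_G: np.ndarray
    omega_R: np.ndarray
    random_effects: pd.DataFrame  # subject x 8, columns = random_effect_labels()
    factor_scores: pd.DataFrame | None = None  # per-visit true latent factors


@dataclass
class CohortDataset:
    """Visit-level records with per-subject grouping.

    ``data`` is long format with at least ``subject_id`` and
    ``visit_time_months`` columns; domain scores live in columns named
    after :data:`mvqol.constants.DOMAINS` when present.
    """

    data: pd.DataFrame
    schema: CovariateSchema = field(default_factory=CovariateSchema)
    truth: CohortTruth | None = None

    def __post_init__(self) -> None:
        for col in (SUBJECT_COL, TIME_COL):
            if col not in self.data.columns:
                raise ValidationError(f"cohort data lacks required column {col!r}")

    # -- basic properties -------------------------------------------------
    @property
    def n_visits(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data[SUBJECT_COL].nunique()

    @property
    def subjects(self) -> np.ndarray:
        return self.data[SUBJECT_COL].unique()

    def by_subject(self):
        """Iterate (subject_id, sub-frame sorted by visit time)."""
        for sid, grp in self.data.groupby(SUBJECT_COL, sort=True):
            yield sid, grp.sort_values(TIME_COL)

    def has_scores(self) -> bool:
        return all(k in self.data.columns for k in DOMAINS)

    def validate_times(self) -> None:
        """Visit times must be strictly increasing within subject."""
        for sid, grp in self.data.groupby(SUBJECT_COL):
            t = np.sort(grp[TIME_COL].to_numpy(dtype=float))
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValidationError(f"subject {sid!r} has non-increasing visit times")

    def copy(self) -> "CohortDataset":
        return CohortDataset(self.data.copy(), self.schema, self.truth)
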