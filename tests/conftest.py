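"""Shared fixtures: compact simulated cohorts for the model tests."""

from __future__ import annotations

import numpy as np
import pytest

from mvqol.constants import DOMAINS
from mvqol.synthetic import SimulationConfig, generate_cohort


def make_config(
    n_subjects: int,
    n_visits: int,
    seed: int = 0,
    beta: dict | None = None,
    omega_G: np.ndarray | None = None,
    omega_R: np.ndarray | None = None,
    covariates: dict | None = None,
) -> SimulationConfig:
    """A minimal balanced-design simulation config (no clinical panel)."""
    if beta is None:
        beta = {k: {"intercept": 10.0, "time": 0.2} for k in DOMAINS}
    kwargs = {}
    if omega_G is not None:
        kwargs["omega_G"] = omega_G
    if omega_R is not None:
        kwargs["omega_R"] = omega_R
    return SimulationConfig(
        n_subjects=n_subjects,
        visit_schedule=np.arange(float(n_visits)),
        visits_mean=n_visits,
        visits_sd=0.0,
        beta=beta,
        covariates=covariates or {},
        clinical_loadings=None,
        seed=seed,
        **kwargs,
    )


def make_cohort(n_subjects: int, n_visits: int, seed: int = 0, **kw):
    return generate_cohort(make_config(n_subjects, n_visits, seed=seed, **kw))


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects x 5 visits, intercept + time only."""
    return make_cohort(30, 5, seed=1)


@pytest.fixture(scope="session")
def medium_fits(small_cohort):
    """Related and independent fits of the small cohort (reused widely)."""
    from mvqol.mvml import ModelSpec, fit_independent, fit_mvml

    spec = ModelSpec()
    related = fit_mvml(small_cohort, spec)
    independent = fit_independent(small_cohort, spec)
    return related, independent
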