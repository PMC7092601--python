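"""Fit statistics, model comparison, effect tables and cross-outcome contrasts.

Information criteria follow the mixed-model reporting conventions in
which the small-sample AIC correction counts level-1 units (visits)
while BIC counts level-2 units (subjects):

    AIC  = -2LL + 2p
    AICC = AIC + 2p(p+1) / (n - p - 1)     n = number of visits
    BIC  = -2LL + p log(m)                 m = number of subjects

with p the total parameter count (fixed effects + free covariance
parameters).  Cross-outcome contrasts test whether one covariate's
effect differs between two outcomes, using the joint fixed-effect
covariance: for contrast vector c, z = c'beta / sqrt(c' Cov(beta) c),
two-sided normal p-value.  No multiplicity correction is applied by
default (a Bonferroni option exists).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DOMAIN_LABELS
from .exceptions import ValidationError
from .mvml import MvmlFit

#: significance stars at the conventional two-sided thresholds
_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class FitStatistics:
    """Information criteria of one fitted model."""

    neg2_loglik: float
    aic: float
    aicc: float  # NaN when n - p - 1 <= 0
    bic: float
    n_params: int
    n_subjects: int
    n_visits: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "-2 Log Likelihood": self.neg2_loglik,
                "AIC": self.aic,
                "AICC": self.aicc,
                "BIC": self.bic,
            }
        )


def information_criteria(
    neg2_loglik: float, n_params: int, n_visits: int, n_subjects: int
) -> tuple[float, float, float]:
    """(AIC, AICC, BIC) from a deviance and the level-1/level-2 counts."""
    aic = neg2_loglik + 2.0 * n_params
    denom = n_visits - n_params - 1
    if denom <= 0:
        warnings.warn("AICC undefined: n - p - 1 <= 0", stacklevel=2)
        aicc = math.nan
    else:
        aicc = aic + 2.0 * n_params * (n_params + 1) / denom
    bic = neg2_loglik + n_params * math.log(n_subjects) if n_subjects > 0 else math.nan
    return aic, aicc, bic


def fit_statistics(fit: MvmlFit) -> FitStatistics:
    """Information criteria for a fitted model."""
    aic, aicc, bic = information_criteria(
        fit.neg2_loglik, fit.n_params, fit.n_visits, fit.n_subjects
    )
    return FitStatistics(
        neg2_loglik=fit.neg2_loglik,
        aic=aic,
        aicc=aicc,
        bic=bic,
        n_params=fit.n_params,
        n_subjects=fit.n_subjects,
        n_visits=fit.n_visits,
    )


@dataclass
class ModelComparison:
    """Side-by-side fit statistics of the independent and related variants."""

    table: pd.DataFrame  # criteria x {Independent Outcome, Related Outcome}
    preferred: str | None  # lower-AIC model, None on a tie
    lr_statistic: float
    lr_df: int


def compare_models(fit_related: MvmlFit, fit_independent: MvmlFit) -> ModelComparison:
    """Compare related vs independent fits on the same data and mean model.

    Preference goes to the lower AIC; the likelihood-ratio statistic
    (df = difference in free covariance parameters, 30 for four
    outcomes) is reported as supplementary evidence.
    """
    if list(fit_related.beta.index) != list(fit_independent.beta.index):
        raise ValidationError("fits have different fixed-effect structures")
    if (fit_related.n_visits, fit_related.n_subjects) != (
        fit_independent.n_visits,
        fit_independent.n_subjects,
    ):
        raise ValidationError("fits come from different datasets")
    cols = {}
    for name, fit in (
        ("Independent Outcome", fit_independent),
        ("Related Outcome", fit_related),
    ):
        cols[name] = fit_statistics(fit).as_series()
    table = pd.DataFrame(cols)
    aic_i = table.loc["AIC", "Independent Outcome"]
    aic_r = table.loc["AIC", "Related Outcome"]
    if math.isclose(aic_i, aic_r, rel_tol=0.0, abs_tol=1e-9):
        preferred = None
    else:
        preferred = "Related Outcome" if aic_r < aic_i else "Independent Outcome"
    lr = fit_independent.neg2_loglik - fit_related.neg2_loglik
    df = fit_related.n_cov_params - fit_independent.n_cov_params
    return ModelComparison(table=table, preferred=preferred, lr_statistic=float(lr), lr_df=df)


def _stars(p: float) -> str:
    for threshold, mark in _STARS:
        if p < threshold:
            return mark
    return ""


def effect_table(fit: MvmlFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per (outcome, term) estimates with 95% CIs and significance stars.

    Terms are split into the baseline block (intercept, time, main
    covariate effects) and the time-slope block (covariate x time
    interactions).  Inference is Wald with the normal reference.
    """
    z975 = stats.norm.ppf(1.0 - alpha / 2.0)
    se = fit.se()
    est = fit.beta
    zval = est / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    rows = []
    for (outcome, term), e in est.items():
        s = se[(outcome, term)]
        p = float(pval[est.index.get_loc((outcome, term))])
        rows.append(
            {
                "outcome": outcome,
                "term": term,
                "block": "slope" if term.endswith(":time") else "baseline",
                "estimate": e,
                "std_error": s,
                "ci_low": e - z975 * s,
                "ci_high": e + z975 * s,
                "p_value": p,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    """A between-outcome difference of one covariate effect."""

    label: str
    term: str
    block: str  # "baseline" | "slope"
    estimate: float
    std_error: float
    statistic: float
    p_value: float


def contrast(
    fit: MvmlFit,
    term: str,
    outcome_a: str,
    outcome_b: str,
    block: str = "baseline",
    bonferroni: int | None = None,
) -> ContrastResult:
    """Test beta_{a,term} - beta_{b,term} between two outcomes.

    ``block="slope"`` contrasts the covariate's time-interaction
    coefficients.  ``bonferroni`` multiplies the p-value by the given
    family size (off by default, matching the uncorrected convention).
    """
    if block not in ("baseline", "slope"):
        raise ValidationError("block must be 'baseline' or 'slope'")
    col = f"{term}:time" if block == "slope" else term
    for outcome in (outcome_a, outcome_b):
        if (outcome, col) not in fit.beta.index:
            raise ValidationError(f"term {col!r} absent for outcome {outcome!r}")
    c = pd.Series(0.0, index=fit.beta.index)
    c[(outcome_a, col)] = 1.0
    c[(outcome_b, col)] = -1.0
    est = float(c @ fit.beta)
    var = float(c @ fit.beta_cov.to_numpy() @ c)
    se = math.sqrt(max(var, 0.0))
    z = est / se if se > 0 else math.nan
    p = 2.0 * float(stats.norm.sf(abs(z))) if se > 0 else math.nan
    if bonferroni:
        p = min(1.0, p * bonferroni)
    label = (
        f"{DOMAIN_LABELS.get(outcome_a, outcome_a)} - "
        f"{DOMAIN_LABELS.get(outcome_b, outcome_b)}"
    )
    return ContrastResult(
        label=label,
        term=term,
        block=block,
        estimate=est,
        std_error=se,
        statistic=z,
        p_value=p,
    )


def contrast_table(fit: MvmlFit, contrasts: list[dict]) -> pd.DataFrame:
    """Evaluate a list of contrast requests into one report table.

    Each request is a dict with keys term, outcome_a, outcome_b and
    optionally block.
    """
    rows = []
    for req in contrasts:
        res = contrast(
            fit,
            req["term"],
            req["outcome_a"],
            req["outcome_b"],
            block=req.get("block", "baseline"),
        )
        rows.append(
            {
                "term": res.term,
                "label": res.label,
                "block": res.block,
                "estimate": res.estimate,
                "std_error": res.std_error,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "stars": _stars(res.p_value),
            }
        )
    return pd.DataFrame(rows)
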