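"""Seed-reproducible synthetic cohorts with the joint growth-curve structure.

The generator emulates a longitudinal HIV cohort (219 women followed
from acute infection through cART) in which four correlated
quality-of-life domain trajectories are observed at every clinic visit:

    y_kjt = x'_tj beta_k + u_kj + v_kj * t + e_kjt ,   k = 1..4

with (u_1j..u_4j, v_1j..v_4j) ~ MVN(0, Omega_G) drawn once per subject,
and the per-visit residual 4-vector (e_1jt..e_4jt) ~ MVN(0, Omega_R)
independent across visits.  Defaults reproduce the study conditions:
219 subjects, a mixed weekly/monthly/quarterly visit schedule averaging
~40 visits, subject-level correlations taken from the published 8x8
correlation estimate (projected to the nearest PSD correlation matrix,
since the printed matrix has one slightly negative eigenvalue), and a
24-variable clinical panel generated from a block latent-factor model.

Each subject draws from an independent random stream derived from
(master seed, subject id), so enlarging a cohort never perturbs
existing subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .constants import (
    COMPLETE_COL,
    DEFAULT_ITEMS_PER_DOMAIN,
    DOMAINS,
    SUBJECT_COL,
    TIME_COL,
    random_effect_labels,
)
from .dataset import CohortDataset, CohortTruth, CovariateSchema
from .exceptions import ValidationError

# --------------------------------------------------------------------------
# default subject-level covariance: published correlation pattern
# --------------------------------------------------------------------------

# Printed order: (b_ind, b_ph, b_psy, b_soc, s_ind, s_ph, s_psy, s_soc).
_PRINTED_CORR = np.array(
    [
        [1.00, 0.49, 0.42, 0.60, -0.60, -0.50, -0.47, -0.48],
        [0.49, 1.00, 0.94, 0.61, -0.66, -0.93, -0.93, -0.65],
        [0.42, 0.94, 1.00, 0.58, -0.53, -0.84, -0.89, -0.56],
        [0.60, 0.61, 0.58, 1.00, -0.51, -0.60, -0.58, -0.69],
        [-0.60, -0.66, -0.53, -0.51, 1.00, 0.84, 0.81, 0.86],
        [-0.50, -0.93, -0.84, -0.60, 0.84, 1.00, 0.90, 0.84],
        [-0.47, -0.93, -0.89, -0.58, 0.81, 0.90, 1.00, 0.81],
        [-0.48, -0.65, -0.56, -0.69, 0.86, 0.84, 0.81, 1.00],
    ]
)
# reorder (ind, ph, psy, soc) -> canonical (ph, psy, ind, soc)
_PERM = [1, 2, 0, 3]
_REORDER = _PERM + [4 + i for i in _PERM]


def nearest_psd_corr(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the diagonal renormalised to
    one.  Used because published correlation tables rounded to two
    decimals need not be PSD.
    """
    sym = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eps, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def default_omega_G() -> np.ndarray:
    """8x8 subject-level covariance: published correlations, unit variances."""
    return nearest_psd_corr(_PRINTED_CORR[np.ix_(_REORDER, _REORDER)])


def default_omega_R(residual_corr: float = 0.4, variance: float = 1.0) -> np.ndarray:
    """Occasion-level residual covariance: exchangeable cross-outcome correlation.

    The study reports no residual covariance estimates; 0.4 is a
    moderate positive residual correlation consistent with the finding
    that the four domain scores remain correlated within occasion.
    """
    k = len(DOMAINS)
    m = np.full((k, k), residual_corr * variance)
    np.fill_diagonal(m, variance)
    return m


# --------------------------------------------------------------------------
# default clinical panel: block loading structure of the 24-variable panel
# --------------------------------------------------------------------------

#: Four independently-factored variable groups.  Loadings follow the
#: published rotated pattern (white blood cell, red blood cell, blood
#: chemistry, protein panels); uniquenesses are 1 - communality.
DEFAULT_CLINICAL_LOADINGS: dict[str, dict[str, Any]] = {
    "white_blood_cell": {
        "factors": ["granulocytes", "mononuclear", "eosinophils_comp"],
        "variables": [
            "leucocyte",
            "neutrophils",
            "lymphocytes",
            "monocytes",
            "eosinophils",
            "basophils",
        ],
        "loadings": [
            [0.925, 0.282, 0.146],
            [0.936, -0.158, 0.022],
            [0.226, 0.838, -0.109],
            [0.635, 0.417, -0.032],
            [0.085, 0.058, 0.947],
            [-0.035, 0.616, 0.339],
        ],
    },
    "red_blood_cell": {
        "factors": ["hb_haematocrit", "rbc_indices"],
        "variables": ["rbc_count", "hb", "haematocrit", "mcv", "mch", "mchc", "rdw"],
        "loadings": [
            [0.946, -0.130],
            [0.886, 0.439],
            [0.919, 0.366],
            [0.075, 0.953],
            [0.024, 0.825],
            [0.201, 0.521],
            [-0.382, -0.592],
        ],
    },
    "blood_chemistry": {
        "factors": ["liver_abnormality", "electrolyte"],
        "variables": ["chloride", "alkaline_phosphatase", "alt", "ast", "sodium", "calcium"],
        "loadings": [
            [-0.023, 0.455],
            [0.174, 0.032],
            [0.829, -0.073],
            [0.967, -0.122],
            [0.103, 0.994],
            [-0.020, 0.213],
        ],
    },
    "protein": {
        "factors": ["lipid", "protein_comp"],
        "variables": ["cholesterol", "ldl", "triglycerides", "ldh", "total_protein"],
        "loadings": [
            [0.971, 0.027],
            [0.917, -0.129],
            [0.360, 0.341],
            [0.052, -0.769],
            [-0.009, 0.670],
        ],
    },
}

# --------------------------------------------------------------------------
# default covariates: baseline cohort composition
# --------------------------------------------------------------------------

# Categorical frequencies follow the published baseline table of the
# 219-woman cohort (normalised); first level = reference category.
DEFAULT_COVARIATES: dict[str, dict[str, Any]] = {
    "marital": {
        "type": "categorical",
        "levels": ["many_partners", "single", "married"],
        "probs": [11 / 219, 34 / 219, 174 / 219],
    },
    "education": {
        "type": "categorical",
        "levels": ["le_grade8", "grade9_10", "gt_grade11"],
        "probs": [16 / 219, 50 / 219, 153 / 219],
    },
    "age_group": {
        "type": "categorical",
        "levels": ["le20", "21_39", "40_59"],
        "probs": [0.15, 0.79, 0.06],
    },
    "tb": {"type": "categorical", "levels": ["yes", "no"], "probs": [18 / 219, 201 / 219]},
    "anemia": {"type": "categorical", "levels": ["yes", "no"], "probs": [11 / 219, 208 / 219]},
    "thrombocytopenia": {
        "type": "categorical",
        "levels": ["no", "yes"],
        "probs": [0.90, 0.10],
    },
    "adverse_event": {
        "type": "categorical",
        "levels": ["severe", "advanced", "mild", "normal"],
        "probs": [9 / 219, 41 / 219, 89 / 219, 80 / 219],
    },
    "sex_drunk": {
        "type": "categorical",
        "levels": ["no", "yes"],
        "probs": [197 / 219, 22 / 219],
    },
    "weight": {
        "type": "continuous",
        "mean": 70.0,
        "sd": 12.0,
        "sd_within": 2.0,
        "time_varying": True,
    },
    "viral_load": {
        "type": "continuous",
        "mean": 4.46,
        "sd": 0.90,
        "sd_within": 0.35,
        "time_varying": True,
    },
}

# Fixed-effect defaults: published point estimates for the intercept and
# time rows plus a subset of covariates with unambiguous printed values.
DEFAULT_BETA: dict[str, dict[str, float]] = {
    "ph": {
        "intercept": 10.8,
        "time": 0.18,
        "viral_load": -0.21,
        "viral_load:time": -0.06,
        "weight": 0.01,
        "weight:time": 0.01,
        "tb[no]": 0.38,
        "anemia[no]": 1.38,
        "thrombocytopenia[yes]": 0.67,
        "age_group[21_39]": -0.34,
        "age_group[21_39]:time": 0.02,
    },
    "psy": {
        "intercept": 9.63,
        "time": 0.21,
        "viral_load": -0.29,
        "viral_load:time": -0.01,
        "weight": 0.01,
        "weight:time": 0.01,
        "tb[no]": 0.01,
        "anemia[no]": -0.61,
        "thrombocytopenia[yes]": 0.52,
        "age_group[21_39]": 0.26,
        "age_group[21_39]:time": 0.0,
    },
    "ind": {
        "intercept": 12.8,
        "time": 0.05,
        "viral_load": -0.09,
        "viral_load:time": -0.001,
        "weight": 0.01,
        "weight:time": 0.001,
        "tb[no]": 0.16,
        "anemia[no]": -0.58,
        "thrombocytopenia[yes]": -2.01,
        "age_group[21_39]": -1.89,
        "age_group[21_39]:time": 0.07,
    },
    "soc": {
        "intercept": 13.5,
        "time": 0.03,
        "viral_load": -0.06,
        "viral_load:time": -0.001,
        "weight": -0.01,
        "weight:time": 0.001,
        "tb[no]": 0.05,
        "anemia[no]": 0.06,
        "thrombocytopenia[yes]": -0.33,
        "age_group[21_39]": -1.25,
        "age_group[21_39]:time": 0.06,
    },
}


def default_visit_schedule() -> np.ndarray:
    """Visit times in months: weekly to 3 mo, monthly to 12 mo, quarterly after.

    Mirrors the acute -> early -> established -> cART phase structure;
    46 scheduled visits over 7 years.
    """
    weekly = np.arange(0.0, 3.0, 0.25)
    monthly = np.arange(3.0, 12.0, 1.0)
    quarterly = np.arange(12.0, 85.0, 3.0)
    return np.concatenate([weekly, monthly, quarterly])


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All generator knobs; defaults encode the emulated study conditions."""

    n_subjects: int = 219
    visit_schedule: np.ndarray = field(default_factory=default_visit_schedule)
    visits_mean: float = 40.0
    visits_sd: float = 8.0
    visits_min: int = 2
    beta: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BETA.items()}
    )
    omega_G: np.ndarray = field(default_factory=default_omega_G)
    omega_R: np.ndarray = field(default_factory=default_omega_R)
    covariates: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
    )
    clinical_loadings: dict[str, dict[str, Any]] | None = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_LOADINGS.items()}
    )
    items_per_domain: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ITEMS_PER_DOMAIN)
    )
    emit_items: bool = False
    likert_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.visits_min < 2:
            raise ValidationError("every subject needs at least two visits")
        for name, m in (("omega_G", self.omega_G), ("omega_R", self.omega_R)):
            m = np.asarray(m, dtype=float)
            if m.shape != (m.shape[0], m.shape[0]) or not np.allclose(m, m.T, atol=1e-10):
                raise ValidationError(f"{name} must be square symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValidationError(f"{name} is not positive semi-definite")
        if np.asarray(self.omega_G).shape != (2 * len(DOMAINS), 2 * len(DOMAINS)):
            raise ValidationError("omega_G must be 8x8 (intercept block then slope block)")
        if np.asarray(self.omega_R).shape != (len(DOMAINS), len(DOMAINS)):
            raise ValidationError("omega_R must be 4x4")
        for name, spec in self.covariates.items():
            if spec.get("type") == "categorical":
                p = np.asarray(spec["probs"], dtype=float)
                if len(p) != len(spec["levels"]):
                    raise ValidationError(f"covariate {name!r}: levels/probs length mismatch")
                if abs(p.sum() - 1.0) > 1e-12:
                    raise ValidationError(
                        f"covariate {name!r}: category frequencies sum to {p.sum()!r}, not 1"
                    )
        if len(self.visit_schedule) < self.visits_min:
            raise ValidationError("visit schedule shorter than visits_min")


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(np.asarray(m, dtype=float))
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _subject_rng(seed: int, subject: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject)]))


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _term_value(term: str, row: dict[str, Any], t: float) -> float:
    """Resolve one fixed-effect term at one visit."""
    if term.endswith(":time"):
        return _term_value(term[:-5], row, t) * t
    if term == "intercept":
        return 1.0
    if term == "time":
        return t
    if "[" in term:
        name, level = term[:-1].split("[")
        return 1.0 if row[name] == level else 0.0
    return float(row[term])


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Draw a full cohort from the joint growth-curve generative model.

    Per subject: one 8-vector of random effects from ``omega_G``; per
    visit: a 4-vector of residuals from ``omega_R``; outcomes are the
    fixed-effect surface plus random intercept, random slope x time,
    and residual.  The returned dataset carries the generating truth.
    """
    config.validate()
    sqrt_G = _psd_sqrt(config.omega_G)
    sqrt_R = _psd_sqrt(config.omega_R)
    schedule = np.asarray(config.visit_schedule, dtype=float)
    labels = random_effect_labels()
    k_out = len(DOMAINS)

    rows: list[dict[str, Any]] = []
    re_rows: list[dict[str, Any]] = []
    factor_rows: list[pd.DataFrame] = []
    for j in range(config.n_subjects):
        rng = _subject_rng(config.seed, j)
        n_vis = int(
            np.clip(
                round(rng.normal(config.visits_mean, config.visits_sd)),
                config.visits_min,
                len(schedule),
            )
        )
        times = schedule[:n_vis]

        cov_base: dict[str, Any] = {}
        cov_subject_mean: dict[str, float] = {}
        for name, spec in config.covariates.items():
            if spec.get("type") == "categorical":
                cov_base[name] = str(
                    rng.choice(spec["levels"], p=np.asarray(spec["probs"], dtype=float))
                )
            else:
                cov_subject_mean[name] = rng.normal(spec["mean"], spec["sd"])

        b = sqrt_G @ rng.standard_normal(2 * k_out)
        u, v = b[:k_out], b[k_out:]
        e = rng.standard_normal((n_vis, k_out)) @ sqrt_R.T

        panel = truth_scores = None
        if config.clinical_loadings is not None:
            panel, truth_scores = generate_clinical_panel(
                config.clinical_loadings, n_vis, rng=rng
            )
            truth_scores.insert(0, SUBJECT_COL, j)
            factor_rows.append(truth_scores)

        re_rows.append({SUBJECT_COL: j, **dict(zip(labels, b))})

        for t_idx, t in enumerate(times):
            row: dict[str, Any] = {SUBJECT_COL: j, TIME_COL: float(t)}
            row.update(cov_base)
            for name, mean in cov_subject_mean.items():
                spec = config.covariates[name]
                if spec.get("time_varying"):
                    row[name] = mean + rng.normal(0.0, spec.get("sd_within", 0.0))
                else:
                    row[name] = mean
            if panel is not None:
                row.update(panel.iloc[t_idx].to_dict())
            for ki, k in enumerate(DOMAINS):
                lp = sum(
                    coef * _term_value(term, row, t)
                    for term, coef in config.beta[k].items()
                )
                y = lp + u[ki] + v[ki] * t + e[t_idx, ki]
                row[k] = y
                if config.emit_items:
                    items = generate_likert_items(
                        float(np.clip(y, 4.0, 20.0)),
                        config.items_per_domain[k],
                        config.likert_noise_sd,
                        rng=rng,
                    )
                    for ii, it in enumerate(items):
                        row[f"dom{ki + 1}_item{ii + 1}"] = it
            row[COMPLETE_COL] = True
            rows.append(row)

    data = pd.DataFrame(rows)
    schema = CovariateSchema(
        {
            name: {
                "type": spec.get("type", "continuous"),
                **({"levels": list(spec["levels"])} if "levels" in spec else {}),
            }
            for name, spec in config.covariates.items()
        }
    )
    truth = CohortTruth(
        beta={k: dict(vv) for k, vv in config.beta.items()},
        omega_G=np.asarray(config.omega_G, dtype=float).copy(),
        omega_R=np.asarray(config.omega_R, dtype=float).copy(),
        random_effects=pd.DataFrame(re_rows).set_index(SUBJECT_COL),
        factor_scores=(
            pd.concat(factor_rows, ignore_index=True) if factor_rows else None
        ),
    )
    return CohortDataset(data, schema, truth)


def generate_likert_items(
    domain_score: float,
    n_items: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Invert the mean-times-four scoring transform into integer items.

    With ``noise_sd = 0`` the items are the integer vector whose
    re-scored value is the nearest attainable score to ``domain_score``
    (attainable scores are 4 * k / n_items for integer totals k).
    Gaussian noise is added per item before rounding/clipping.
    """
    if not 4.0 <= domain_score <= 20.0:
        raise ValidationError(f"domain_score {domain_score!r} outside [4, 20]")
    if n_items < 1:
        raise ValidationError("n_items must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    target_mean = domain_score / 4.0
    total = int(round(target_mean * n_items))
    total = min(max(total, n_items), 5 * n_items)
    q, r = divmod(total, n_items)
    items = np.full(n_items, q, dtype=float)
    if r:
        items[:r] += 1.0
    if noise_sd > 0:
        items = items + rng.normal(0.0, noise_sd, size=n_items)
    return np.clip(np.rint(items), 1, 5).astype(int)


def generate_clinical_panel(
    loading_spec: dict[str, dict[str, Any]] | None = None,
    n_obs: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the observed clinical panel ``x = Lambda f + eps``.

    Factors are independent standard normals within each variable
    group; groups are mutually independent (they are factored
    separately downstream).  Uniquenesses are 1 - communality, floored
    at 0.02.  Returns ``(panel, true_factor_scores)``; each observed
    column has mean 0 and unit total variance by construction.
    """
    if loading_spec is None:
        loading_spec = DEFAULT_CLINICAL_LOADINGS
    if rng is None:
        rng = np.random.default_rng(seed)
    panels = {}
    scores = {}
    for group, spec in loading_spec.items():
        lam = np.asarray(spec["loadings"], dtype=float)
        if lam.shape[0] != len(spec["variables"]):
            raise ValidationError(f"group {group!r}: loadings/variables mismatch")
        communality = (lam**2).sum(axis=1)
        if np.any(communality > 1.0 + 1e-12):
            raise ValidationError(
                f"group {group!r}: communalities exceed 1 — loadings invalid"
            )
        if "uniquenesses" in spec:
            uniq = np.asarray(spec["uniquenesses"], dtype=float)
            if np.any(uniq < 0):
                raise ValidationError(f"group {group!r}: negative uniqueness")
        else:
            uniq = np.clip(1.0 - communality, 0.02, None)
        f = rng.standard_normal((n_obs, lam.shape[1]))
        eps = rng.standard_normal((n_obs, lam.shape[0])) * np.sqrt(uniq)
        x = f @ lam.T + eps
        for i, name in enumerate(spec["variables"]):
            panels[name] = x[:, i]
        for i, name in enumerate(spec["factors"]):
            scores[name] = f[:, i]
    return pd.DataFrame(panels), pd.DataFrame(scores)


def inject_missing_responses(
    dataset: CohortDataset, fraction: float, seed: int = 0
) -> CohortDataset:
    """Blank >= 1 domain score on exactly round(fraction * n_visits) visits.

    Affected visits are flagged incomplete so the filter stage can
    count and drop them.  fraction must lie in [0, 1).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("fraction must be in [0, 1)")
    out = dataset.copy()
    n = len(out.data)
    n_hit = int(round(fraction * n))
    if n_hit == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_hit, replace=False)
    dom_choice = rng.integers(0, len(DOMAINS), size=n_hit)
    cols = list(DOMAINS)
    df = out.data
    positions = df.index[idx]
    for pos, d in zip(positions, dom_choice):
        df.loc[pos, cols[d]] = math.nan
    if COMPLETE_COL not in df.columns:
        df[COMPLETE_COL] = True
    df.loc[positions, COMPLETE_COL] = False
    return out
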