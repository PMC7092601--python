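"""Exploratory factor analysis of the clinical panel.

Compresses the 24 clinical variables into latent component scores:
variables are standardized, factors extracted by maximum likelihood on
the correlation matrix (principal-axis fallback, PCA mode via config),
the number of factors retained by the Kaiser criterion (correlation
eigenvalues > 1), loadings varimax-rotated, and per-observation scores
computed by the regression (Thomson) method.  Loading strengths are
labelled on absolute value: strong > 0.6, moderate in [0.4, 0.6],
weak < 0.4.

Each clinical variable group (white blood cell, red blood cell, blood
chemistry, protein) is factored separately, reproducing the four
independent sub-analyses that yield nine named components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

STRONG_THRESHOLD = 0.6
MODERATE_THRESHOLD = 0.4

#: canonical component name for each clinical variable's dominant factor
_COMPONENT_OF_VARIABLE = {
    "leucocyte": "granulocytes",
    "neutrophils": "granulocytes",
    "monocytes": "granulocytes",
    "lymphocytes": "mononuclear",
    "basophils": "mononuclear",
    "eosinophils": "eosinophils_comp",
    "rbc_count": "hb_haematocrit",
    "hb": "hb_haematocrit",
    "haematocrit": "hb_haematocrit",
    "mcv": "rbc_indices",
    "mch": "rbc_indices",
    "mchc": "rbc_indices",
    "rdw": "rbc_indices",
    "alt": "liver_abnormality",
    "ast": "liver_abnormality",
    "sodium": "electrolyte",
    "chloride": "electrolyte",
    "calcium": "electrolyte",
    "cholesterol": "lipid",
    "ldl": "lipid",
    "triglycerides": "lipid",
    "ldh": "protein_comp",
    "total_protein": "protein_comp",
    "alkaline_phosphatase": "liver_abnormality",
}


@dataclass
class FactorModel:
    """A fitted (rotated) factor model for one variable group."""

    loadings: pd.DataFrame  # variables x retained factors (rotated)
    rotation: np.ndarray  # orthogonal rotation applied to raw loadings
    eigenvalues: np.ndarray  # correlation-matrix eigenvalues, descending
    retained: int
    strength_labels: pd.DataFrame  # same shape as loadings, str labels
    scoring_weights: pd.DataFrame  # variables x factors
    means: pd.Series
    sds: pd.Series
    extraction: str = "ml"
    uniquenesses: pd.Series | None = None

    @property
    def variables(self) -> list[str]:
        return list(self.loadings.index)


def kaiser_retain(eigenvalues: np.ndarray) -> int:
    """Number of correlation eigenvalues strictly greater than 1 (floor 1)."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValidationError("empty eigenvalue vector")
    if np.any(np.diff(ev) > 1e-12):
        raise ValidationError("eigenvalues must be sorted in descending order")
    n = int((ev > 1.0).sum())
    if n == 0:
        warnings.warn(
            "no eigenvalue exceeds 1; retaining a single factor", stacklevel=2
        )
        return 1
    return n


def classify_loading(loading: float) -> str:
    """Label one loading by |value|: strong > 0.6, moderate [0.4, 0.6], weak < 0.4."""
    a = abs(float(loading))
    if a > STRONG_THRESHOLD:
        return "strong"
    if a >= MODERATE_THRESHOLD:
        return "moderate"
    return "weak"


def varimax_rotate(
    loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (SVD algorithm).

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation``.
    Communalities (row sums of squares) are invariant.  Sign
    convention: the largest-|loading| entry of each rotated factor is
    made positive.  A single factor rotates by the identity.
    """
    lam = np.asarray(loadings, dtype=float)
    p, k = lam.shape
    if k < 2:
        rot = np.ones((1, 1))
        out = lam.copy()
    else:
        rot = np.eye(k)
        var = 0.0
        for _ in range(max_iter):
            lr = lam @ rot
            u, s, vt = np.linalg.svd(
                lam.T @ (lr**3 - (lr * (lr**2).sum(axis=0)) / p)
            )
            rot = u @ vt
            new_var = s.sum()
            if new_var <= var * (1.0 + tol):
                break
            var = new_var
        out = lam @ rot
    # sign convention
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] *= -1.0
            rot[:, j] *= -1.0
    return out, rot


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: sum over factors of variance of squared loadings."""
    lam2 = np.asarray(loadings, dtype=float) ** 2
    return float((lam2.var(axis=0)).sum())


def _ml_objective(psi: np.ndarray, corr: np.ndarray, k: int) -> float:
    """Profile ML discrepancy over uniquenesses (loadings concentrated out).

    With S* = Psi^{-1/2} R Psi^{-1/2} and eigenvalues l_1 >= ... >= l_p,
    the profiled discrepancy is sum_{i>k} (l_i - log l_i - 1).
    """
    sc = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(sc, sc)
    ev = np.sort(np.linalg.eigvalsh(sstar))[::-1][k:]
    ev = np.clip(ev, 1e-12, None)
    return float(np.sum(ev - np.log(ev) - 1.0))


def _ml_loadings(psi: np.ndarray, corr: np.ndarray, k: int) -> np.ndarray:
    sc = np.sqrt(psi)
    sstar = corr / np.outer(sc, sc)
    w, v = np.linalg.eigh(sstar)
    idx = np.argsort(w)[::-1][:k]
    lam_star = v[:, idx] * np.sqrt(np.clip(w[idx] - 1.0, 0.0, None))
    return lam_star * sc[:, None]


def _ml_extract(corr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, str]:
    """ML factor extraction: bounded optimisation over uniquenesses.

    Profiles the loadings out of the normal-theory discrepancy and
    minimises over psi in [0.005, 1], which keeps the solution away
    from Heywood boundaries; principal-axis fallback on failure.
    """
    from scipy import optimize

    p = corr.shape[0]
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        _ml_objective,
        psi0,
        args=(corr, k),
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not np.all(np.isfinite(res.x)):
        warnings.warn(
            "maximum-likelihood extraction failed to converge; "
            "falling back to principal-axis factoring",
            stacklevel=3,
        )
        return _principal_axis(corr, k) + ("pa",)
    lam = _ml_loadings(res.x, corr, k)
    return lam, res.x, "ml"


def _principal_axis(corr: np.ndarray, k: int, n_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    r = corr.copy()
    comm = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))  # SMC start
    for _ in range(n_iter):
        np.fill_diagonal(r, comm)
        w, v = np.linalg.eigh(r)
        idx = np.argsort(w)[::-1][:k]
        lam = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
        new_comm = (lam**2).sum(axis=1)
        if np.max(np.abs(new_comm - comm)) < 1e-8:
            comm = new_comm
            break
        comm = new_comm
    return lam, 1.0 - comm


def fit_factor_model(
    panel: pd.DataFrame,
    n_factors: int | None = None,
    extraction: str = "ml",
    score_method: str = "regression",
) -> FactorModel:
    """Fit one variable group: standardize, extract, retain, rotate, score.

    ``extraction`` is "ml" (default), "pa" or "pca"; ``n_factors``
    overrides Kaiser retention.  Raises on < 3 variables, < 50
    observations, constant columns, or a singular correlation matrix.
    """
    if panel.shape[1] < 3:
        raise ValidationError("need at least 3 variables for factor analysis")
    if panel.shape[0] < 50:
        raise ValidationError("need at least 50 observations for factor analysis")
    sds = panel.std(ddof=1)
    constant = sds.index[sds < 1e-12].tolist()
    if constant:
        raise ValidationError(f"constant columns cannot be factored: {constant}")
    means = panel.mean()
    z = ((panel - means) / sds).to_numpy()
    corr = np.corrcoef(z, rowvar=False)
    cond = np.linalg.cond(corr)
    if cond > 1e10:
        # name the most collinear pair for the error message
        off = np.abs(corr - np.eye(len(corr)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValidationError(
            "singular correlation matrix; most collinear columns: "
            f"{panel.columns[i]!r}, {panel.columns[j]!r}"
        )
    eigenvalues = np.sort(np.linalg.eigvalsh(corr))[::-1]
    k = n_factors if n_factors is not None else kaiser_retain(eigenvalues)

    if extraction == "pca":
        w, v = np.linalg.eigh(corr)
        idx = np.argsort(w)[::-1][:k]
        lam = v[:, idx] * np.sqrt(w[idx])
        uniq = 1.0 - (lam**2).sum(axis=1)
        used = "pca"
    elif extraction == "pa":
        lam, uniq = _principal_axis(corr, k)
        used = "pa"
    else:
        lam, uniq, used = _ml_extract(corr, k)

    rotated, rot = varimax_rotate(lam)
    factor_names = [f"factor{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(rotated, index=panel.columns, columns=factor_names)
    labels = loadings.abs().map(classify_loading)

    if score_method == "bartlett":
        psi_inv = np.diag(1.0 / np.clip(uniq, 1e-6, None))
        w_mat = psi_inv @ rotated @ np.linalg.inv(rotated.T @ psi_inv @ rotated)
    else:  # regression (Thomson)
        w_mat = np.linalg.solve(corr, rotated)
    weights = pd.DataFrame(w_mat, index=panel.columns, columns=factor_names)

    return FactorModel(
        loadings=loadings,
        rotation=rot,
        eigenvalues=eigenvalues,
        retained=k,
        strength_labels=labels,
        scoring_weights=weights,
        means=means,
        sds=sds,
        extraction=used,
        uniquenesses=pd.Series(uniq, index=panel.columns),
    )


def compute_factor_scores(model: FactorModel, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-observation factor scores from a fitted model.

    Standardizes with the fitting-sample constants and applies the
    scoring weights; on the fitting sample each score has mean 0.
    """
    missing = [c for c in model.variables if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel lacks fitted variables: {missing}")
    z = (panel[model.variables] - model.means) / model.sds
    return pd.DataFrame(
        z.to_numpy() @ model.scoring_weights.to_numpy(),
        index=panel.index,
        columns=model.scoring_weights.columns,
    )


def name_components(model: FactorModel) -> dict[str, str]:
    """Map each fitted factor to a canonical clinical component name.

    A factor is named after the component of its top-loading variable;
    collisions fall back to positional names.
    """
    names: dict[str, str] = {}
    used: set[str] = set()
    for col in model.loadings.columns:
        top_var = model.loadings[col].abs().idxmax()
        cand = _COMPONENT_OF_VARIABLE.get(top_var, col)
        if cand in used:
            cand = col
        names[col] = cand
        used.add(cand)
    return names


def fit_clinical_components(
    panel: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    extraction: str = "ml",
) -> tuple[dict[str, FactorModel], pd.DataFrame]:
    """Factor each clinical variable group separately; return scores.

    ``groups`` maps group name -> variable list; default groups follow
    the 24-variable panel layout.  Returns ``(models, score_frame)``
    where the score frame's columns carry canonical component names.
    """
    if groups is None:
        from .synthetic import DEFAULT_CLINICAL_LOADINGS

        groups = {
            g: list(spec["variables"]) for g, spec in DEFAULT_CLINICAL_LOADINGS.items()
        }
    models: dict[str, FactorModel] = {}
    score_frames: list[pd.DataFrame] = []
    for group, variables in groups.items():
        missing = [v for v in variables if v not in panel.columns]
        if missing:
            raise ValidationError(f"group {group!r}: panel lacks {missing}")
        model = fit_factor_model(panel[variables], extraction=extraction)
        models[group] = model
        scores = compute_factor_scores(model, panel)
        scores = scores.rename(columns=name_components(model))
        score_frames.append(scores)
    return models, pd.concat(score_frames, axis=1)


def scree_table(model: FactorModel) -> pd.DataFrame:
    """Eigenvalue table for scree inspection (exported as data, not a plot)."""
    ev = model.eigenvalues
    return pd.DataFrame(
        {
            "component": np.arange(1, len(ev) + 1),
            "eigenvalue": ev,
            "proportion_variance": ev / ev.sum(),
            "cumulative_variance": np.cumsum(ev) / ev.sum(),
        }
    )


def plot_scree(model: FactorModel, path: str) -> None:
    """Write a scree figure to ``path`` (helper; core export is scree_table)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = scree_table(model)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(tab["component"], tab["eigenvalue"], "o-")
    ax.axhline(1.0, color="grey", ls="--", lw=1)
    ax.set_xlabel("Component")
    ax.set_ylabel("Eigenvalue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
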