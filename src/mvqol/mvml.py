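"""Multivariate multilevel (joint growth-curve) model estimation.

Four longitudinal outcomes y_kjt share one subject-level random-effect
distribution: each subject j carries a random intercept u_kj and random
time slope v_kj per outcome, with

    (u_1j..u_Kj, v_1j..v_Kj) ~ MVN(0, Omega_G)          (2K x 2K)
    (e_1jt..e_Kjt)           ~ MVN(0, Omega_R) per visit  (K x K)

so the marginal law of subject j's stacked response (visit-major,
outcomes innermost) is Y_j ~ MVN(X_j beta, V_j) with

    V_j = Z_j Omega_G Z_j' + I_{n_j} (x) Omega_R .

Estimation is marginal maximum likelihood: beta is profiled out by GLS
at each covariance parameter value, and the profile deviance is
minimised by quasi-Newton iteration over a log-Cholesky
parameterisation (log diagonal, free off-diagonal), which decodes to a
PSD covariance for every unconstrained parameter vector.  The gradient
is analytic.  The "independent outcome" restriction zeroes every
cross-outcome covariance (Omega_G block-diagonal in per-outcome 2x2
blocks, Omega_R diagonal), which is exactly four separate univariate
linear mixed models fitted jointly.

REML is available via ``ModelSpec.estimation = "reml"``; the default is
ML so that deviances are comparable across fixed-effect structures and
between the related and independent variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .constants import DOMAINS, SUBJECT_COL, TIME_COL, random_effect_labels
from .dataset import CohortDataset, CovariateSchema
from .exceptions import ConvergenceWarning, ValidationError

logger = logging.getLogger(__name__)

_GRAD_TOL = 1e-4  # max-norm convergence criterion on the deviance gradient
_JITTER0 = 1e-8  # initial ridge (x mean diagonal) on Cholesky failure


# --------------------------------------------------------------------------
# model specification and design
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """What enters each outcome's mean and which covariance variant to fit.

    ``fixed_terms`` are covariate names entering every outcome's
    baseline (intercept) block; ``slope_terms`` enter the time-
    interaction block.  Categorical covariates are dummy-encoded
    against the first level of the schema (the reference category).
    """

    outcomes: tuple[str, ...] = DOMAINS
    fixed_terms: list[str] = field(default_factory=list)
    slope_terms: list[str] = field(default_factory=list)
    time_var: str = TIME_COL
    related: bool = True
    estimation: str = "ml"  # "ml" | "reml"

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)


@dataclass
class _Group:
    """Subjects sharing one visit-time vector (one V matrix)."""

    times: np.ndarray  # (n_vis,)
    subjects: list
    Y: np.ndarray  # (n_subj, q)
    X: np.ndarray  # (n_subj, q, p)
    Z: np.ndarray  # (q, 2K)


@dataclass
class Design:
    """Per-subject stacked design, grouped by shared time vector."""

    groups: list[_Group]
    labels: list[tuple[str, str]]  # (outcome, term), length p
    outcomes: tuple[str, ...]
    subjects: list  # fitting order
    n_visits: int
    dropped_subjects: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def K(self) -> int:
        return len(self.outcomes)


def _expand_terms(
    terms: list[str], schema: CovariateSchema
) -> list[tuple[str, str | None]]:
    """Expand covariate names to design columns: (column_label, level)."""
    out: list[tuple[str, str | None]] = []
    for t in terms:
        if schema.is_categorical(t):
            levels = schema.spec[t]["levels"]
            for lev in levels[1:]:  # first level is the reference
                out.append((f"{t}[{lev}]", lev))
        else:
            out.append((t, None))
    return out


def build_design(dataset: CohortDataset, spec: ModelSpec) -> Design:
    """Stack each subject's visits into (Y_j, X_j, Z_j).

    Row order is visit-major with outcomes innermost; the fixed design
    is block-diagonal in outcome within each visit; Z_j maps the 2K
    random effects to (visit, outcome) cells.  Subjects with any
    missing covariate are excluded (logged).  Input row order within a
    subject is irrelevant: visits are sorted by time internally.
    """
    K = spec.n_outcomes
    schema = dataset.schema
    if spec.time_var not in dataset.data.columns:
        raise ValidationError(f"time variable {spec.time_var!r} not in data")
    for k in spec.outcomes:
        if k not in dataset.data.columns:
            raise ValidationError(f"outcome column {k!r} not in data")

    base_cols = _expand_terms(spec.fixed_terms, schema)
    slope_cols = _expand_terms(spec.slope_terms, schema)
    per_outcome_terms = (
        ["intercept"]
        + [c for c, _ in base_cols]
        + ["time"]
        + [f"{c}:time" for c, _ in slope_cols]
    )
    labels = [(k, term) for k in spec.outcomes for term in per_outcome_terms]
    n_per = len(per_outcome_terms)
    p = K * n_per

    def _check_level(name: str, value) -> None:
        if value not in schema.spec[name]["levels"]:
            raise ValidationError(
                f"covariate {name!r}: unseen category {value!r} "
                f"(schema levels: {schema.spec[name]['levels']})"
            )

    cov_names = list(
        dict.fromkeys(list(spec.fixed_terms) + list(spec.slope_terms))
    )

    grouped: dict[tuple, _Group] = {}
    subjects: list = []
    dropped: list = []
    n_visits = 0
    for sid, grp in dataset.data.groupby(SUBJECT_COL, sort=True):
        grp = grp.sort_values(spec.time_var)
        if grp[cov_names + list(spec.outcomes)].isna().any().any():
            dropped.append(sid)
            continue
        t = grp[spec.time_var].to_numpy(dtype=float)
        n_vis = len(t)
        q = K * n_vis
        y = np.empty(q)
        X = np.zeros((q, p))
        Z = np.zeros((q, 2 * K))
        scores = grp[list(spec.outcomes)].to_numpy(dtype=float)
        # per-visit covariate row values for each expanded column
        def col_values(cols: list[tuple[str, str | None]]) -> np.ndarray:
            vals = np.empty((n_vis, len(cols)))
            for ci, (label, level) in enumerate(cols):
                if level is None:
                    vals[:, ci] = grp[label].to_numpy(dtype=float)
                else:
                    name = label.split("[")[0]
                    for val in grp[name]:
                        _check_level(name, val)
                    vals[:, ci] = (grp[name] == level).to_numpy(dtype=float)
            return vals

        bvals = col_values(base_cols)
        svals = col_values(slope_cols)
        for ti in range(n_vis):
            for ki in range(K):
                r = ti * K + ki
                y[r] = scores[ti, ki]
                off = ki * n_per
                X[r, off] = 1.0
                X[r, off + 1 : off + 1 + len(base_cols)] = bvals[ti]
                X[r, off + 1 + len(base_cols)] = t[ti]
                X[r, off + 2 + len(base_cols) : off + n_per] = svals[ti] * t[ti]
                Z[r, ki] = 1.0
                Z[r, K + ki] = t[ti]
        key = tuple(np.round(t, 9))
        if key not in grouped:
            grouped[key] = _Group(times=t, subjects=[], Y=[], X=[], Z=Z)  # type: ignore[arg-type]
        g = grouped[key]
        g.subjects.append(sid)
        g.Y.append(y)  # type: ignore[attr-defined]
        g.X.append(X)  # type: ignore[attr-defined]
        subjects.append(sid)
        n_visits += n_vis

    if dropped:
        logger.info("build_design: excluded %d subjects with missing covariates", len(dropped))
    groups = []
    for g in grouped.values():
        groups.append(
            _Group(
                times=g.times,
                subjects=g.subjects,
                Y=np.asarray(g.Y),
                X=np.asarray(g.X),
                Z=g.Z,
            )
        )
    return Design(
        groups=groups,
        labels=labels,
        outcomes=spec.outcomes,
        subjects=subjects,
        n_visits=n_visits,
        dropped_subjects=dropped,
    )


# --------------------------------------------------------------------------
# covariance parameterisation (log-Cholesky)
# --------------------------------------------------------------------------


@dataclass
class CovarianceStructure:
    """Log-Cholesky parameterisation of (Omega_G, Omega_R).

    Free entries of the lower Cholesky factors are listed as
    (matrix, row, col); diagonal entries are stored on the log scale so
    any real parameter vector decodes to a PSD pair.  The related
    variant frees every lower-triangular entry (2K(2K+1)/2 + K(K+1)/2
    parameters); the independent variant frees only the per-outcome
    (intercept, slope) blocks of Omega_G and the diagonal of Omega_R.
    """

    K: int
    related: bool = True

    def __post_init__(self) -> None:
        K = self.K
        entries: list[tuple[str, int, int]] = []
        if self.related:
            for i in range(2 * K):
                for j in range(i + 1):
                    entries.append(("G", i, j))
            for i in range(K):
                for j in range(i + 1):
                    entries.append(("R", i, j))
        else:
            for k in range(K):
                entries.append(("G", k, k))
                entries.append(("G", K + k, k))
                entries.append(("G", K + k, K + k))
            for k in range(K):
                entries.append(("R", k, k))
        self.entries = entries

    @property
    def n_params(self) -> int:
        return len(self.entries)

    def decode(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """theta -> lower Cholesky factors (L_G, L_R)."""
        K = self.K
        LG = np.zeros((2 * K, 2 * K))
        LR = np.zeros((K, K))
        for val, (mat, i, j) in zip(theta, self.entries):
            tgt = LG if mat == "G" else LR
            tgt[i, j] = np.exp(val) if i == j else val
        return LG, LR

    def decode_cov(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        LG, LR = self.decode(theta)
        return LG @ LG.T, LR @ LR.T

    def encode(self, omega_G: np.ndarray, omega_R: np.ndarray) -> np.ndarray:
        """Covariance pair -> theta (ridged Cholesky for near-singular input)."""

        def chol(m: np.ndarray) -> np.ndarray:
            m = np.asarray(m, dtype=float)
            ridge = 1e-10 * max(np.mean(np.diag(m)), 1.0)
            for _ in range(12):
                try:
                    return np.linalg.cholesky(m + ridge * np.eye(len(m)))
                except np.linalg.LinAlgError:
                    ridge *= 10.0
            raise ValidationError("covariance matrix is not PSD")

        LG, LR = chol(omega_G), chol(omega_R)
        theta = np.empty(self.n_params)
        for m_idx, (mat, i, j) in enumerate(self.entries):
            src = LG if mat == "G" else LR
            theta[m_idx] = np.log(max(src[i, j], 1e-8)) if i == j else src[i, j]
        return theta

    def bounds(self) -> list[tuple[float | None, float | None]]:
        # log-sd bounded away from +-inf keeps boundary fits well-behaved
        return [
            (-8.0, 8.0) if i == j else (None, None) for (_, i, j) in self.entries
        ]


# --------------------------------------------------------------------------
# profile deviance and analytic gradient
# --------------------------------------------------------------------------


class _Objective:
    """Profile −2 log-likelihood over theta, with analytic gradient."""

    def __init__(self, design: Design, struct: CovarianceStructure, reml: bool = False):
        self.design = design
        self.struct = struct
        self.reml = reml
        self.n_total = sum(g.Y.size for g in design.groups)
        self.p = design.p

    def _factor(self, V: np.ndarray):
        """Cholesky with escalating jitter; None on final failure."""
        jitter = _JITTER0 * np.mean(np.diag(V))
        for attempt in range(4):
            try:
                return linalg.cho_factor(
                    V if attempt == 0 else V + jitter * np.eye(len(V)), lower=True
                )
            except linalg.LinAlgError:
                jitter *= 10.0
        logger.warning("Cholesky of V failed after jitter escalation")
        return None

    def evaluate(self, theta: np.ndarray, want_grad: bool = True):
        """Return (neg2ll, grad, beta, H) where H = sum X'V^-1 X."""
        struct = self.struct
        LG, LR = struct.decode(theta)
        omega_G, omega_R = LG @ LG.T, LR @ LR.T
        K = struct.K
        p = self.p
        H = np.zeros((p, p))
        xty = np.zeros(p)
        logdet = 0.0
        cache = []
        for g in self.design.groups:
            n_vis = len(g.times)
            V = g.Z @ omega_G @ g.Z.T + np.kron(np.eye(n_vis), omega_R)
            cf = self._factor(V)
            if cf is None:
                return np.inf, np.zeros(struct.n_params), None, None
            q = V.shape[0]
            Vinv = linalg.cho_solve(cf, np.eye(q))
            logdet += 2.0 * np.sum(np.log(np.diag(cf[0]))) * len(g.subjects)
            VinvX = np.einsum("qr,nrp->nqp", Vinv, g.X)
            H += np.einsum("nqp,nqk->pk", g.X, VinvX)
            xty += np.einsum("nqp,nq->p", VinvX, g.Y)
            cache.append((g, Vinv, VinvX, cf))
        try:
            Hc = linalg.cho_factor(H)
        except linalg.LinAlgError:
            # ill-conditioned GLS system at an extreme covariance value:
            # report an infinite deviance so the optimizer backs off
            # (genuine rank deficiency is diagnosed once, at fit entry)
            return np.inf, np.zeros(struct.n_params), None, None
        beta = linalg.cho_solve(Hc, xty)

        quad = 0.0
        MG = np.zeros((2 * K, 2 * K))
        MR = np.zeros((K, K))
        QG = np.zeros((2 * K, 2 * K))
        QR = np.zeros((K, K))
        Hinv = linalg.cho_solve(Hc, np.eye(p)) if (want_grad and self.reml) else None
        for g, Vinv, VinvX, cf in cache:
            n_vis = len(g.times)
            n_subj = len(g.subjects)
            Rg = g.Y - g.X @ beta
            Wg = Rg @ Vinv
            quad += float(np.einsum("nq,nq->", Wg, Rg))
            if not want_grad:
                continue
            A = g.Z.T @ Vinv @ g.Z
            B = np.einsum("tktl->kl", Vinv.reshape(n_vis, K, n_vis, K))
            P = Wg @ g.Z  # (n_subj, 2K)
            MG += n_subj * A - P.T @ P
            W4 = Wg.reshape(n_subj, n_vis, K)
            MR += n_subj * B - np.einsum("ntk,ntl->kl", W4, W4)
            if self.reml:
                D = VinvX  # (n, q, p)
                ZD = np.einsum("qm,nqp->nmp", g.Z, D)  # (n, 2K, p)
                QG += np.einsum("nmp,pk,nlk->ml", ZD, Hinv, ZD)
                DH = np.einsum("nqp,pk->nqk", D, Hinv)
                S_full = np.einsum("nqk,nrk->qr", DH, D)
                QR += np.einsum("tktl->kl", S_full.reshape(n_vis, K, n_vis, K))

        n2ll = logdet + quad + self.n_total * np.log(2.0 * np.pi)
        if self.reml:
            n2ll += 2.0 * np.sum(np.log(np.diag(Hc[0])))
            n2ll -= self.p * np.log(2.0 * np.pi)
        if not want_grad:
            return n2ll, None, beta, H

        if self.reml:
            MG = MG - QG
            MR = MR - QR
        grad = np.empty(struct.n_params)
        GG = MG @ LG
        GR = MR @ LR
        for m, (mat, i, j) in enumerate(struct.entries):
            src = GG if mat == "G" else GR
            Lsrc = LG if mat == "G" else LR
            g_val = 2.0 * src[i, j]
            if i == j:
                g_val *= Lsrc[i, j]  # chain rule through the log-diagonal
            grad[m] = g_val
        return n2ll, grad, beta, H


# --------------------------------------------------------------------------
# public likelihood evaluation
# --------------------------------------------------------------------------


def marginal_loglik(
    data: Design | CohortDataset,
    omega_G: np.ndarray,
    omega_R: np.ndarray,
    beta: np.ndarray | None = None,
    spec: ModelSpec | None = None,
    reml: bool = False,
) -> float:
    """Marginal log-likelihood at given covariance matrices.

    ``data`` may be a prebuilt :class:`Design` or a cohort (then
    ``spec`` is required).  With ``beta=None`` the GLS profile value is
    used.  Computed per subject via the Cholesky factor of V_j.
    """
    design = data if isinstance(data, Design) else build_design(data, spec or ModelSpec())
    omega_G = np.asarray(omega_G, dtype=float)
    omega_R = np.asarray(omega_R, dtype=float)
    n_total = sum(g.Y.size for g in design.groups)
    logdet = 0.0
    quad = 0.0
    H = np.zeros((design.p, design.p))
    xty = np.zeros(design.p)
    cache = []
    for g in design.groups:
        n_vis = len(g.times)
        V = g.Z @ omega_G @ g.Z.T + np.kron(np.eye(n_vis), omega_R)
        cf = linalg.cho_factor(V, lower=True)
        Vinv = linalg.cho_solve(cf, np.eye(V.shape[0]))
        logdet += 2.0 * np.sum(np.log(np.diag(cf[0]))) * len(g.subjects)
        cache.append((g, Vinv))
        if beta is None:
            VinvX = np.einsum("qr,nrp->nqp", Vinv, g.X)
            H += np.einsum("nqp,nqk->pk", g.X, VinvX)
            xty += np.einsum("nqp,nq->p", VinvX, g.Y)
    b = np.linalg.solve(H, xty) if beta is None else np.asarray(beta, dtype=float)
    for g, Vinv in cache:
        Rg = g.Y - g.X @ b
        quad += float(np.einsum("nq,qr,nr->", Rg, Vinv, Rg))
    ll = -0.5 * (logdet + quad + n_total * np.log(2.0 * np.pi))
    if reml:
        ll -= 0.5 * np.linalg.slogdet(H)[1]
        ll += 0.5 * design.p * np.log(2.0 * np.pi)
    return float(ll)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class MvmlFit:
    """A fitted multivariate multilevel model."""

    beta: pd.Series  # MultiIndex (outcome, term)
    beta_cov: pd.DataFrame
    omega_G: pd.DataFrame
    omega_R: pd.DataFrame
    neg2_loglik: float
    theta: np.ndarray
    converged: bool
    gradient_norm: float
    n_subjects: int
    n_visits: int
    n_cov_params: int
    spec: ModelSpec
    estimation: str = "ml"
    _design: Design | None = None

    @property
    def n_params(self) -> int:
        return len(self.beta) + self.n_cov_params

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.beta_cov.to_numpy())), index=self.beta.index
        )


def _start_theta(design: Design, struct: CovarianceStructure) -> np.ndarray:
    """Moment-flavoured start: half the outcome variance to each level."""
    K = design.K
    var_y = np.zeros(K)
    n = 0
    for g in design.groups:
        Y4 = g.Y.reshape(len(g.subjects), len(g.times), K)
        var_y += Y4.var(axis=(0, 1)) * len(g.subjects)
        n += len(g.subjects)
    var_y = np.clip(var_y / max(n, 1), 1e-2, None)
    omega_G = np.diag(np.concatenate([0.5 * var_y, 0.05 * np.ones(K)]))
    omega_R = np.diag(0.5 * var_y)
    return struct.encode(omega_G, omega_R)


def _projected_grad_norm(
    theta: np.ndarray, grad: np.ndarray, bounds: list[tuple[float | None, float | None]]
) -> float:
    """Max-norm of the KKT-projected gradient (components pushing into an
    active bound do not count against convergence)."""
    g = grad.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None and theta[i] <= lo + 1e-9 and g[i] > 0:
            g[i] = 0.0
        if hi is not None and theta[i] >= hi - 1e-9 and g[i] < 0:
            g[i] = 0.0
    return float(np.max(np.abs(g)))


def _minimise(obj: _Objective, theta0: np.ndarray, maxiter: int, precision: str = "standard"):
    fun = lambda th: obj.evaluate(th, want_grad=True)[:2]  # noqa: E731
    res = optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=obj.struct.bounds(),
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-7},
    )
    # polish: restart L-BFGS from the stopping point (fresh Hessian memory)
    # until the deviance stops improving — the surface is very flat near
    # boundary optima and single runs routinely stall short
    for _ in range(6):
        if np.max(np.abs(res.jac)) <= _GRAD_TOL / 10:
            break
        res2 = optimize.minimize(
            fun,
            res.x,
            jac=True,
            method="L-BFGS-B",
            bounds=obj.struct.bounds(),
            options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-8},
        )
        improved = res.fun - res2.fun
        if res2.fun <= res.fun:
            res = res2
        if improved < 1e-9:
            break
    if np.max(np.abs(res.jac)) > _GRAD_TOL / 10:
        # final trust-region polish localises the optimum on flat surfaces
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="delta_grad")
            res3 = optimize.minimize(
            fun,
            res.x,
            jac=True,
                method="trust-constr",
                bounds=optimize.Bounds(
                    *map(
                        np.array,
                        zip(
                            *[
                                (
                                    lo if lo is not None else -np.inf,
                                    hi if hi is not None else np.inf,
                                )
                                for lo, hi in obj.struct.bounds()
                            ]
                        ),
                    )
                ),
                options={"maxiter": 200, "gtol": 1e-9, "xtol": 1e-14},
            )
        if res3.fun <= res.fun:
            res3.jac = obj.evaluate(res3.x, want_grad=True)[1]
            res = res3
    if precision == "high":
        # repeated tight trust-region rounds localise the optimum to ~1e-7
        # in deviance; used where reparameterisation-exactness matters
        for _ in range(4):
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message="delta_grad")
                r = optimize.minimize(
                    fun,
                    res.x,
                    jac=True,
                    method="trust-constr",
                    options={"maxiter": 500, "gtol": 1e-12, "xtol": 1e-16},
                )
            if r.fun < res.fun - 1e-12:
                r.jac = obj.evaluate(r.x, want_grad=True)[1]
                res = r
            else:
                break
    return res


def _fit(
    dataset: CohortDataset,
    spec: ModelSpec,
    related: bool,
    start: np.ndarray | None = None,
    maxiter: int = 600,
    precision: str = "standard",
) -> MvmlFit:
    design = build_design(dataset, spec)
    if design.n_subjects < 2:
        raise ValidationError("need at least 2 subjects to fit")
    # rank check on the OLS Gram matrix, once per fit
    gram = np.zeros((design.p, design.p))
    for g in design.groups:
        gram += np.einsum("nqp,nqk->pk", g.X, g.X)
    ev = np.linalg.eigvalsh(gram)
    if ev[0] < 1e-10 * max(ev[-1], 1.0):
        w, v = np.linalg.eigh(gram)
        idx = np.argsort(np.abs(v[:, 0]))[::-1][:3]
        cols = [f"{o}:{t}" for (o, t) in (design.labels[i] for i in idx)]
        raise ValidationError(
            "fixed-effect design is rank deficient; offending columns: "
            + ", ".join(cols)
        )
    struct = CovarianceStructure(design.K, related=related)
    reml = spec.estimation.lower() == "reml"
    obj = _Objective(design, struct, reml=reml)

    bounds = struct.bounds()
    theta0 = start if start is not None else _start_theta(design, struct)
    res = _minimise(obj, theta0, maxiter, precision=precision)
    n2ll, grad, _, _ = obj.evaluate(res.x, want_grad=True)
    gnorm = _projected_grad_norm(res.x, grad, bounds)
    theta, best = res.x, n2ll
    converged = gnorm <= _GRAD_TOL
    if not converged:
        # one restart from a perturbed point; if it cannot improve the
        # deviance (relative 1e-8) the flat optimum is confirmed
        rng = np.random.default_rng(0)
        res2 = _minimise(
            obj, res.x + rng.normal(0.0, 0.05, size=len(res.x)), maxiter, precision=precision
        )
        n2b, g2, _, _ = obj.evaluate(res2.x, want_grad=True)
        if n2b < best:
            theta, best = res2.x, n2b
            gnorm = _projected_grad_norm(res2.x, g2, bounds)
        converged = (
            gnorm <= _GRAD_TOL or abs(n2b - n2ll) <= 1e-8 * (1.0 + abs(n2ll))
        )
    if not converged:
        warnings.warn(
            f"optimizer stopped with deviance-gradient max-norm {gnorm:.2e}",
            ConvergenceWarning,
            stacklevel=3,
        )

    n2ll, _, beta, H = obj.evaluate(theta, want_grad=False)
    omega_G, omega_R = struct.decode_cov(theta)
    beta_cov = np.linalg.inv(H)
    idx = pd.MultiIndex.from_tuples(design.labels, names=["outcome", "term"])
    re_labels = random_effect_labels(design.outcomes)
    fit = MvmlFit(
        beta=pd.Series(beta, index=idx),
        beta_cov=pd.DataFrame(beta_cov, index=idx, columns=idx),
        omega_G=pd.DataFrame(omega_G, index=re_labels, columns=re_labels),
        omega_R=pd.DataFrame(
            omega_R, index=list(design.outcomes), columns=list(design.outcomes)
        ),
        neg2_loglik=float(n2ll),
        theta=theta,
        converged=converged,
        gradient_norm=gnorm,
        n_subjects=design.n_subjects,
        n_visits=design.n_visits,
        n_cov_params=struct.n_params,
        spec=replace(spec, related=related),
        estimation="reml" if reml else "ml",
        _design=design,
    )
    return fit


def fit_independent(
    dataset: CohortDataset,
    spec: ModelSpec,
    maxiter: int = 600,
    precision: str = "standard",
) -> MvmlFit:
    """Fit the independent-outcome restriction (four univariate LMMs jointly)."""
    return _fit(dataset, spec, related=False, maxiter=maxiter, precision=precision)


def fit_mvml(
    dataset: CohortDataset,
    spec: ModelSpec | None = None,
    warm_start: bool = True,
    maxiter: int = 600,
    precision: str = "standard",
) -> MvmlFit:
    """Fit the related-outcome multivariate multilevel model by ML.

    The related fit is warm-started from the independent restriction
    (block-diagonal Omega_G, diagonal Omega_R plus a small ridge),
    which stabilises the full covariance optimisation.
    """
    spec = spec or ModelSpec()
    if not spec.related:
        return fit_independent(dataset, spec, maxiter=maxiter)
    start = None
    if warm_start:
        ind = fit_independent(dataset, spec, maxiter=maxiter)
        K = ind.spec.n_outcomes
        struct = CovarianceStructure(K, related=True)
        ridge_G = 1e-4 * np.mean(np.diag(ind.omega_G.to_numpy()))
        ridge_R = 1e-4 * np.mean(np.diag(ind.omega_R.to_numpy()))
        start = struct.encode(
            ind.omega_G.to_numpy() + ridge_G * np.eye(2 * K),
            ind.omega_R.to_numpy() + ridge_R * np.eye(K),
        )
    return _fit(dataset, spec, related=True, start=start, maxiter=maxiter, precision=precision)


# --------------------------------------------------------------------------
# post-fit summaries
# --------------------------------------------------------------------------


@dataclass
class RandomEffectCorrelations:
    """Correlation matrix of the 2K random effects, with defined-ness mask."""

    matrix: pd.DataFrame
    undefined: list[str]


def random_effect_correlations(fit: MvmlFit, zero_tol: float = 1e-10) -> RandomEffectCorrelations:
    """D^{-1/2} Omega_G D^{-1/2}; zero-variance rows are flagged undefined.

    Undefined rows/columns are reported as NaN deliberately (with the
    affected labels listed) rather than propagating a division by zero.
    """
    omega = fit.omega_G.to_numpy()
    d = np.diag(omega).copy()
    labels = list(fit.omega_G.index)
    undefined = [labels[i] for i in range(len(d)) if d[i] < zero_tol]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = omega / np.sqrt(np.outer(d, d))
    for i in range(len(d)):
        if d[i] < zero_tol:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
        else:
            corr[i, i] = 1.0
    return RandomEffectCorrelations(
        matrix=pd.DataFrame(corr, index=labels, columns=labels), undefined=undefined
    )


def _fit_design(fit: MvmlFit, dataset: CohortDataset | None) -> Design:
    if dataset is None:
        if fit._design is None:
            raise ValidationError("fit carries no design; pass the dataset")
        return fit._design
    return build_design(dataset, fit.spec)


def predict_blups(fit: MvmlFit, dataset: CohortDataset | None = None) -> pd.DataFrame:
    """Empirical-Bayes predictions of each subject's 2K random effects.

    b_j = Omega_G Z_j' V_j^{-1} (Y_j - X_j beta); with Omega_G = 0 all
    predictions are exactly zero, and predictions shrink toward zero
    relative to per-subject least squares.
    """
    design = _fit_design(fit, dataset)
    omega_G = fit.omega_G.to_numpy()
    omega_R = fit.omega_R.to_numpy()
    beta = fit.beta.to_numpy()
    rows = {}
    for g in design.groups:
        n_vis = len(g.times)
        V = g.Z @ omega_G @ g.Z.T + np.kron(np.eye(n_vis), omega_R)
        Vinv = np.linalg.inv(V)
        Rg = g.Y - g.X @ beta
        B = Rg @ Vinv @ g.Z @ omega_G.T  # (n_subj, 2K)
        for sid, b in zip(g.subjects, B):
            rows[sid] = b
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=random_effect_labels(design.outcomes)
    )
    out.index.name = SUBJECT_COL
    return out.sort_index()


def transformed_residuals(
    fit: MvmlFit, dataset: CohortDataset | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cholesky-standardised residuals and their normal Q-Q table.

    Per subject r_j = L_j^{-1}(Y_j - X_j beta) with V_j = L_j L_j'; under
    a correct model the concatenated residuals are approximately iid
    standard normal.  The Q-Q table pairs empirical quantiles with
    standard-normal theoretical quantiles.
    """
    design = _fit_design(fit, dataset)
    omega_G = fit.omega_G.to_numpy()
    omega_R = fit.omega_R.to_numpy()
    beta = fit.beta.to_numpy()
    chunks = []
    for g in design.groups:
        n_vis = len(g.times)
        V = g.Z @ omega_G @ g.Z.T + np.kron(np.eye(n_vis), omega_R)
        L = np.linalg.cholesky(V)
        Rg = g.Y - g.X @ beta
        # solve L r* = r for each subject
        res = linalg.solve_triangular(L, Rg.T, lower=True).T
        chunks.append(res.ravel())
    resid = np.concatenate(chunks)
    srt = np.sort(resid)
    n = len(srt)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo, "empirical": srt})
    return resid, qq
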