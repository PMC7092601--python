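"""The joint growth-curve estimator: design, likelihood, fitting, diagnostics."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import block_diag
from scipy.stats import multivariate_normal

from mvqol.constants import DOMAINS, SUBJECT_COL, TIME_COL
from mvqol.dataset import CohortDataset
from mvqol.exceptions import ValidationError
from mvqol.mvml import (
    CovarianceStructure,
    ModelSpec,
    build_design,
    fit_independent,
    fit_mvml,
    marginal_loglik,
    predict_blups,
    random_effect_correlations,
    transformed_residuals,
)

from conftest import make_cohort, make_config


def _dense_loglik(coh: CohortDataset, omega_G, omega_R) -> float:
    """Independent oracle: assemble each subject's covariance elementwise
    (no Kronecker shortcut), profile beta by dense GLS, evaluate the MVN
    density with scipy."""
    K = 4
    Ys, Xs, Vs = [], [], []
    for _, grp in coh.data.groupby(SUBJECT_COL):
        grp = grp.sort_values(TIME_COL)
        times = grp[TIME_COL].to_numpy()
        n = len(times)
        y = np.empty(n * K)
        X = np.zeros((n * K, 2 * K))
        V = np.empty((n * K, n * K))
        for t in range(n):
            for k in range(K):
                r = t * K + k
                y[r] = grp.iloc[t][DOMAINS[k]]
                X[r, 2 * k] = 1.0
                X[r, 2 * k + 1] = times[t]
                for s in range(n):
                    for l in range(K):
                        V[r, s * K + l] = (
                            omega_G[k, l]
                            + times[t] * omega_G[K + k, l]
                            + times[s] * omega_G[k, K + l]
                            + times[t] * times[s] * omega_G[K + k, K + l]
                            + (omega_R[k, l] if t == s else 0.0)
                        )
        Ys.append(y)
        Xs.append(X)
        Vs.append(V)
    Y = np.concatenate(Ys)
    Xf = np.vstack(Xs)
    Vf = block_diag(*Vs)
    Vinv = np.linalg.inv(Vf)
    beta = np.linalg.solve(Xf.T @ Vinv @ Xf, Xf.T @ Vinv @ Y)
    return float(multivariate_normal.logpdf(Y, mean=Xf @ beta, cov=Vf))


class TestBuildDesign:
    def test_two_visit_layout_matches_hand_computation(self):
        coh = make_cohort(1, 2, seed=0)
        design = build_design(coh, ModelSpec())
        (g,) = design.groups
        times = g.times
        assert g.X.shape == (1, 8, 8) and g.Z.shape == (8, 8)
        X, Z = g.X[0], g.Z
        for t in range(2):
            for k in range(4):
                r = t * 4 + k
                expect_x = np.zeros(8)
                expect_x[2 * k] = 1.0
                expect_x[2 * k + 1] = times[t]
                np.testing.assert_allclose(X[r], expect_x)
                expect_z = np.zeros(8)
                expect_z[k] = 1.0
                expect_z[4 + k] = times[t]
                np.testing.assert_allclose(Z[r], expect_z)

    def test_row_order_within_subject_is_irrelevant(self):
        coh = make_cohort(3, 4, seed=1)
        shuffled = CohortDataset(
            coh.data.sample(frac=1.0, random_state=0).reset_index(drop=True),
            coh.schema,
        )
        d1 = build_design(coh, ModelSpec())
        d2 = build_design(shuffled, ModelSpec())
        for g1, g2 in zip(d1.groups, d2.groups):
            np.testing.assert_allclose(g1.Y, g2.Y)
            np.testing.assert_allclose(g1.X, g2.X)

    def test_dimensions_on_toy_fixture(self):
        df = pd.DataFrame(
            {
                SUBJECT_COL: [0, 0, 1, 1, 1, 2, 2],
                TIME_COL: [0.0, 1.0, 0.0, 1.0, 2.0, 0.0, 2.0],
                **{k: 10.0 for k in DOMAINS},
            }
        )
        design = build_design(CohortDataset(df), ModelSpec())
        sizes = sorted(g.Y.shape for g in design.groups)
        # 4*n_j responses per subject; p = 4 outcomes x (intercept, time)
        assert design.p == 8
        assert design.n_visits == 7
        assert {g.Y.shape[1] for g in design.groups} == {8, 12}

    def test_missing_covariate_excludes_subject(self):
        coh = make_cohort(4, 3, seed=2)
        coh.data["extra"] = 1.0
        coh.data.loc[coh.data[SUBJECT_COL] == 2, "extra"] = np.nan
        coh.schema.spec["extra"] = {"type": "continuous"}
        spec = ModelSpec(fixed_terms=["extra"])
        design = build_design(coh, spec)
        assert design.dropped_subjects == [2]
        assert design.n_subjects == 3

    def test_unseen_category_rejected(self):
        coh = make_cohort(
            4,
            3,
            seed=2,
            covariates={
                "tb": {"type": "categorical", "levels": ["yes", "no"], "probs": [0.5, 0.5]}
            },
        )
        coh.data.loc[0, "tb"] = "maybe"
        with pytest.raises(ValidationError, match="unseen category"):
            build_design(coh, ModelSpec(fixed_terms=["tb"]))


class TestMarginalLoglik:
    def test_single_observation_standard_normal_density(self):
        df = pd.DataFrame(
            {SUBJECT_COL: [0], TIME_COL: [0.0], "ph": [10.0]}
        )
        spec = ModelSpec(outcomes=("ph",))
        design = build_design(CohortDataset(df), spec)
        ll = marginal_loglik(
            design,
            np.zeros((2, 2)),
            np.array([[1.0]]),
            beta=np.array([10.0, 0.0]),
        )
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coh = make_cohort(3, 2, seed=seed)
        A = rng.normal(size=(8, 8))
        omega_G = A @ A.T / 8
        B = rng.normal(size=(4, 4))
        omega_R = B @ B.T / 4 + 0.5 * np.eye(4)
        ours = marginal_loglik(build_design(coh, ModelSpec()), omega_G, omega_R)
        assert ours == pytest.approx(_dense_loglik(coh, omega_G, omega_R), abs=1e-8)

    def test_block_diagonal_equals_sum_of_univariate_likelihoods(self):
        coh = make_cohort(5, 3, seed=4)
        rng = np.random.default_rng(9)
        blocks, sigmas = [], []
        for _ in range(4):
            a = rng.normal(size=(2, 2))
            blocks.append(a @ a.T + 0.1 * np.eye(2))
            sigmas.append(0.5 + rng.random())
        omega_G = np.zeros((8, 8))
        for k, blk in enumerate(blocks):
            omega_G[k, k] = blk[0, 0]
            omega_G[k, 4 + k] = omega_G[4 + k, k] = blk[0, 1]
            omega_G[4 + k, 4 + k] = blk[1, 1]
        omega_R = np.diag(sigmas)
        joint = marginal_loglik(build_design(coh, ModelSpec()), omega_G, omega_R)
        total = 0.0
        for k, outcome in enumerate(DOMAINS):
            d_k = build_design(coh, ModelSpec(outcomes=(outcome,)))
            total += marginal_loglik(d_k, blocks[k], np.array([[sigmas[k]]]))
        assert joint == pytest.approx(total, abs=1e-8)


class TestFitting:
    def test_recovery_under_pure_residual_noise(self):
        # truth: no subject heterogeneity, unit residual variance
        coh = make_cohort(
            200, 8, seed=5, omega_G=np.zeros((8, 8)), omega_R=np.eye(4)
        )
        fit = fit_mvml(coh, ModelSpec())
        assert np.all(np.diag(fit.omega_G.to_numpy()) < 0.08)
        np.testing.assert_allclose(
            np.diag(fit.omega_R.to_numpy()), 1.0, atol=0.12
        )
        se = fit.se()
        for k in DOMAINS:
            assert abs(fit.beta[(k, "intercept")] - 10.0) < 2 * se[(k, "intercept")] + 1e-9
            assert abs(fit.beta[(k, "time")] - 0.2) < 2 * se[(k, "time")] + 1e-9

    def test_related_never_worse_than_independent(self, medium_fits):
        related, independent = medium_fits
        assert related.neg2_loglik <= independent.neg2_loglik + 1e-6

    def test_parameter_count_bookkeeping(self, medium_fits):
        related, independent = medium_fits
        assert related.n_cov_params == 46
        assert independent.n_cov_params == 16
        assert related.n_params == len(related.beta) + 46
        assert CovarianceStructure(4, related=True).n_params == 46
        assert CovarianceStructure(4, related=False).n_params == 16

    def test_independent_fit_equals_statsmodels_univariate_lmms(self):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM

        coh = make_cohort(40, 6, seed=3)
        ours = fit_independent(coh, ModelSpec())
        omega_G = np.zeros((8, 8))
        omega_R = np.zeros((4, 4))
        total = 0.0
        for ki, k in enumerate(DOMAINS):
            exog = sm.add_constant(coh.data[[TIME_COL]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = MixedLM(
                    coh.data[k], exog, groups=coh.data[SUBJECT_COL], exog_re=exog
                ).fit(reml=False, method="lbfgs", maxiter=2000)
            total += -2 * m.llf
            cov = m.cov_re.to_numpy()
            omega_G[ki, ki] = cov[0, 0]
            omega_G[ki, 4 + ki] = omega_G[4 + ki, ki] = cov[0, 1]
            omega_G[4 + ki, 4 + ki] = cov[1, 1]
            omega_R[ki, ki] = m.scale
        # route 1: our likelihood at the oracle's optimum reproduces it
        ll_at_sm = marginal_loglik(build_design(coh, ModelSpec()), omega_G, omega_R)
        assert -2 * ll_at_sm == pytest.approx(total, abs=1e-6)
        # route 2: our optimiser finds at least as good an optimum
        assert ours.neg2_loglik <= total + 1e-4

    def test_cross_correlated_data_separates_the_variants(self):
        omega = np.eye(8)
        for i, j in [(4, 5), (4, 6), (5, 6)]:
            omega[i, j] = omega[j, i] = 0.8
        for rep in range(3):
            coh = make_cohort(60, 6, seed=100 + rep, omega_G=omega)
            rel = fit_mvml(coh, ModelSpec())
            ind = fit_independent(coh, ModelSpec())
            assert ind.neg2_loglik - rel.neg2_loglik > 10.0

    def test_time_origin_shift_leaves_deviance_unchanged(self):
        coh = make_cohort(25, 5, seed=6)
        shift = 3.0
        shifted = CohortDataset(coh.data.copy(), coh.schema, coh.truth)
        shifted.data[TIME_COL] = shifted.data[TIME_COL] - shift
        # analytic invariance: transform (beta, Omega_G) for the new origin
        omega_G = np.array(make_config(1, 2).omega_G)
        omega_R = np.array(make_config(1, 2).omega_R)
        T = np.eye(8)
        for k in range(4):
            T[k, 4 + k] = shift
        omega_G_shift = T @ omega_G @ T.T
        beta = np.array([10.0, 0.2] * 4)
        beta_shift = np.array([10.0 + shift * 0.2, 0.2] * 4)
        ll0 = marginal_loglik(build_design(coh, ModelSpec()), omega_G, omega_R, beta=beta)
        ll1 = marginal_loglik(
            build_design(shifted, ModelSpec()), omega_G_shift, omega_R, beta=beta_shift
        )
        assert ll0 == pytest.approx(ll1, abs=1e-8)
        # fitted deviance is invariant too (high-precision optimisation:
        # the property concerns the likelihood surface, so the optimum must
        # be localised beyond the default optimizer resolution)
        f0 = fit_mvml(coh, ModelSpec(), precision="high")
        f1 = fit_mvml(shifted, ModelSpec(), precision="high")
        assert f0.neg2_loglik == pytest.approx(f1.neg2_loglik, abs=1e-6)

    def test_correlation_bias_shrinks_with_sample_size(self):
        omega = np.eye(8)
        omega[0, 1] = omega[1, 0] = 0.7
        errs = {}
        for n in (50, 400):
            e = []
            for rep in range(3):
                coh = make_cohort(n, 6, seed=200 + rep, omega_G=omega)
                fit = fit_mvml(coh, ModelSpec())
                corr = random_effect_correlations(fit).matrix.to_numpy()
                e.append(abs(corr[0, 1] - 0.7))
            errs[n] = np.mean(e)
        assert errs[400] < errs[50]

    def test_reml_variant_runs_and_differs_from_ml(self):
        coh = make_cohort(25, 4, seed=8)
        ml = fit_independent(coh, ModelSpec())
        reml = fit_independent(coh, ModelSpec(estimation="reml"))
        assert reml.converged
        # REML subject-level variances exceed ML's (degrees-of-freedom
        # correction acts on the between-subject components here)
        assert np.trace(reml.omega_G.to_numpy()) > np.trace(ml.omega_G.to_numpy())


class TestRandomEffectCorrelations:
    def test_diagonal_covariance_gives_identity(self, medium_fits):
        related, _ = medium_fits
        fake = dataclasses.replace(
            related,
            omega_G=pd.DataFrame(
                np.diag(np.arange(1.0, 9.0)),
                index=related.omega_G.index,
                columns=related.omega_G.columns,
            ),
        )
        corr = random_effect_correlations(fake).matrix.to_numpy()
        np.testing.assert_allclose(corr, np.eye(8), atol=1e-12)

    def test_unit_diagonal_and_psd(self, medium_fits):
        related, _ = medium_fits
        res = random_effect_correlations(related)
        m = res.matrix.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.all(np.abs(m) <= 1.0 + 1e-10)
        assert np.linalg.eigvalsh(m).min() > -1e-8
        assert res.undefined == []

    def test_zero_variance_component_reported_as_undefined(self, medium_fits):
        related, _ = medium_fits
        omega = related.omega_G.to_numpy().copy()
        omega[3, :] = 0.0
        omega[:, 3] = 0.0
        fake = dataclasses.replace(
            related,
            omega_G=pd.DataFrame(
                omega, index=related.omega_G.index, columns=related.omega_G.columns
            ),
        )
        res = random_effect_correlations(fake)
        assert res.undefined == ["intercept_soc"]
        assert res.matrix.iloc[3].isna().all()
        assert res.matrix.iloc[0, 1] == pytest.approx(
            omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
        )


class TestBlupsAndResiduals:
    def test_zero_covariance_gives_zero_blups(self, small_cohort, medium_fits):
        related, _ = medium_fits
        fake = dataclasses.replace(
            related,
            omega_G=pd.DataFrame(
                np.zeros((8, 8)),
                index=related.omega_G.index,
                columns=related.omega_G.columns,
            ),
        )
        blups = predict_blups(fake, small_cohort)
        np.testing.assert_allclose(blups.to_numpy(), 0.0, atol=1e-14)

    def test_blups_center_near_zero_and_track_truth(self):
        coh = make_cohort(100, 10, seed=10)
        fit = fit_mvml(coh, ModelSpec())
        blups = predict_blups(fit, coh)
        assert np.all(np.abs(blups.mean()) < 0.15)
        truth = coh.truth.random_effects
        r = np.corrcoef(blups["slope_ph"], truth.loc[blups.index, "slope_ph"])[0, 1]
        assert r > 0.8

    def test_residuals_reduce_to_raw_when_model_is_white(self, small_cohort):
        # with Omega_G = 0 and Omega_R = I at the true beta, the Cholesky
        # standardisation is the identity
        beta_truth = pd.Series(
            [10.0, 0.2] * 4,
            index=pd.MultiIndex.from_tuples(
                [(k, t) for k in DOMAINS for t in ("intercept", "time")],
                names=["outcome", "term"],
            ),
        )
        fit0 = fit_mvml(small_cohort, ModelSpec())
        fake = dataclasses.replace(
            fit0,
            beta=beta_truth,
            omega_G=pd.DataFrame(
                np.zeros((8, 8)), index=fit0.omega_G.index, columns=fit0.omega_G.columns
            ),
            omega_R=pd.DataFrame(
                np.eye(4), index=fit0.omega_R.index, columns=fit0.omega_R.columns
            ),
        )
        resid, _ = transformed_residuals(fake, small_cohort)
        t = small_cohort.data[TIME_COL].to_numpy()
        raw = np.column_stack(
            [small_cohort.data[k].to_numpy() - (10.0 + 0.2 * t) for k in DOMAINS]
        )
        assert np.sort(resid) == pytest.approx(np.sort(raw.ravel()), abs=1e-10)

    def test_residual_variance_near_one_on_large_sample(self):
        coh = make_cohort(150, 10, seed=12)  # 6000 scalar observations
        fit = fit_mvml(coh, ModelSpec())
        resid, qq = transformed_residuals(fit)
        assert 0.9 <= resid.var() <= 1.1
        assert abs(resid.mean()) < 0.05
        assert len(qq) == len(resid)
        assert qq["empirical"].is_monotonic_increasing

    def test_residual_normality_calibration(self):
        # fitted-model standardisation yields approximately N(0,1) residuals
        passes = 0
        n_reps = 20
        for rep in range(n_reps):
            coh = make_cohort(30, 4, seed=300 + rep)
            fit = fit_mvml(coh, ModelSpec())
            resid, _ = transformed_residuals(fit)
            d = stats.kstest(resid, "norm").statistic
            crit = 1.358 / np.sqrt(len(resid))  # 5% two-sided KS critical value
            passes += d < crit
        assert passes >= 0.9 * n_reps
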