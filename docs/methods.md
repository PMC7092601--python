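# Methods

## The model

`mvqol` estimates a joint (multivariate) multilevel growth-curve model
for the four WHOQOL-HIV BREF domain scores — physical health (PH),
psychological (PS), level of independence (LI), social relationships
(SR) — measured repeatedly on the same subjects:

    y_kjt = x'_tj β_k + u_kj + v_kj · t + e_kjt ,   k = 1..4

for subject *j* at visit time *t* (months since enrolment).  Each
subject carries one random intercept and one random time slope per
domain; the eight effects are drawn jointly,

    (u_1j..u_4j, v_1j..v_4j) ~ MVN(0, Ω_G)   (8×8),

and the four occasion-level residuals are drawn jointly per visit,

    (e_1jt..e_4jt) ~ MVN(0, Ω_R)   (4×4),

independently across visits.  The *independent-outcome* restriction
zeroes every cross-domain covariance (Ω_G block-diagonal in per-domain
2×2 blocks, Ω_R diagonal) and is exactly four separate univariate
linear mixed models; comparing the two variants by deviance/AIC tests
whether the domains are genuinely coupled.

Random effects are ordered intercept-block first, then slope-block,
both in the domain order (PH, PS, LI, SR), everywhere in the package.

## Estimation

- **Marginal ML with β profiled out.**  The marginal law per subject is
  Y_j ~ MVN(X_j β, V_j), V_j = Z_j Ω_G Z_j′ + I ⊗ Ω_R, with responses
  stacked visit-major (outcomes innermost) so the residual part has the
  natural Kronecker form.  At each covariance value β is the GLS
  solution; the profile deviance is minimised over the covariance
  parameters.  ML (not REML) is the default so deviances are
  comparable between the related and independent variants; REML is
  available via `ModelSpec(estimation="reml")`.
- **Log-Cholesky parameterisation.**  Ω_G and Ω_R are parameterised by
  the lower Cholesky factor with log-transformed diagonal: every
  unconstrained parameter vector decodes to a PSD pair (46 free
  parameters for the related model, 16 for the independent one).
  Log-standard-deviations are bounded in [−8, 8] so boundary fits
  (variance → 0) terminate cleanly.
- **Analytic gradient.**  The profile-deviance gradient is computed in
  closed form (envelope theorem: the GLS β term vanishes), reducing a
  46-parameter fit to a few hundred cheap evaluations.  Subjects
  sharing a visit-time vector share one V factorisation.
- **Optimisation and convergence.**  L-BFGS-B with restarts until the
  deviance stops improving, then a trust-region polish.  A fit is
  declared converged when the KKT-projected deviance gradient max-norm
  is ≤ 1e−4, or when a perturbed restart cannot improve the deviance
  beyond a relative 1e−8 (flat optima at variance boundaries routinely
  end in the second state).  `precision="high"` adds repeated tight
  trust-region rounds, localising the optimum to ~1e−7 in deviance;
  the default profile resolves it to ~1e−5, which is far below any
  reported digit but matters when verifying exact invariances such as
  time-origin reparameterisation.
- **Warm start.**  The related fit starts from the independent
  solution (plus a 1e−4 relative ridge), mirroring the
  independent-then-related workflow and stabilising the 46-parameter
  optimisation.
- **Jitter.**  If a V Cholesky fails, a ridge of 1e−8 × mean diagonal
  is added, escalating tenfold at most three times before the
  evaluation returns +∞ to the optimizer.
- **Inference.**  Wald, with Cov(β̂) = (Σ X′V⁻¹X)⁻¹ and the normal
  reference distribution (the package reports 95% CIs as ±1.96·SE; no
  Satterthwaite correction).  Cross-outcome contrasts test
  β_{a,term} − β_{b,term} with the joint covariance; p-values are
  two-sided and uncorrected by default (a Bonferroni option exists).

## Fit statistics

AIC = −2LL + 2p; AICC = AIC + 2p(p+1)/(n − p − 1) with **n = visits**
(level-1 units); BIC = −2LL + p·log(m) with **m = subjects** (level-2
units); p counts fixed effects plus free covariance parameters.  The
mixed n/m conventions are the ones under which published
multilevel-model fit-statistic tables of this design are internally
consistent, and match common mixed-procedure output.  Model preference
goes to the lower AIC; the likelihood-ratio statistic (df = 30 for the
four-outcome related-vs-independent comparison) is reported as
supplementary evidence.

## Scoring and filters

A domain score is 4 × mean of its 5-point Likert items, giving the
4–20 range.  A domain is scorable when ≥ 80% of its items are present
(the instrument literature's usual completeness rule; configurable);
the mean is over present items.  A visit is incomplete if any of the
four domains is unscorable.  Pipeline filter order is fixed:
incomplete visits are dropped first, then subjects left with fewer
than two visits are removed — completeness can only reduce visit
counts, so this order is the conservative composition.  Item counts
per domain default to (4, 5, 4, 4), the published WHOQOL-HIV BREF
structure for these four domains; the instrument's religion/spirituality
domain is excluded by construction.  Scores are kept at full precision
for modelling; rounding happens only in reports.

## Clinical-panel factor analysis

The 24 clinical variables are compressed group-by-group (white blood
cell, red blood cell, blood chemistry, protein — four independent
sub-analyses) into nine named components.  Variables are standardized;
factors are extracted by maximum likelihood — the normal-theory
discrepancy profiled over loadings and minimised over uniquenesses
bounded in [0.005, 1], which keeps solutions off Heywood boundaries
(principal-axis fallback; PCA mode via config).  The number of factors
is the count of correlation-matrix eigenvalues strictly greater than 1
(Kaiser; floor of one with a warning), the scree eigenvalue table is
exported as data.  Loadings are varimax-rotated (orthogonal;
communality-preserving; the largest-|loading| entry per factor is made
positive) and labelled on absolute value: strong > 0.6, moderate in
the closed interval [0.4, 0.6], weak < 0.4.  Factor scores use the
regression (Thomson) method by default, Bartlett via config.

## The synthetic cohort generator

The generator emulates a prospective HIV cohort of 219 women followed
from acute infection through treatment, with everything downstream
needs: correlated domain trajectories, Likert item emission, a latent-
factor clinical panel, and missing-response injection.

- **Visit schedule**: weekly to 3 months, monthly to 12 months,
  quarterly thereafter (46 scheduled visits over 7 years); per-subject
  follow-up truncates the shared schedule to give mean ≈ 40 visits
  (minimum 2).  Time is months since enrolment, zero at first visit.
- **Subject-level covariance Ω_G**: the published 8×8 correlation
  estimate with unit variances.  The printed matrix has one slightly
  negative eigenvalue (≈ −0.026; two-decimal rounding), so the default
  projects it to the nearest PSD correlation matrix (eigenvalue
  clipping + diagonal renormalisation).  **Ω_R**: no residual
  covariance is published; the default uses unit variances with a
  common cross-domain residual correlation of 0.4 — a moderate
  positive value consistent with domains remaining correlated within
  occasion.
- **Fixed effects**: published point estimates for the intercept and
  time rows plus a subset of covariates with unambiguous printed
  values; covariate distributions mirror the published baseline table
  (categorical frequencies out of 219; viral load and weight are
  time-varying continuous draws).
- **Clinical panel**: x = Λf + ε with the published rotated block
  loadings as Λ, f ~ N(0, I) per group, uniquenesses 1 − communality
  (floored at 0.02), giving unit total variance per variable.
- **Reproducibility**: each subject draws from an independent stream
  keyed by (master seed, subject id), so enlarging a cohort never
  perturbs existing subjects and equal seeds give byte-identical
  output.

What the generator does **not** emulate: informative dropout,
measurement-error drift, visit-time jitter between subjects, floor/
ceiling effects of bounded scores (trajectories are Gaussian and may
exceed 4–20 unless items are emitted), non-normal residuals, or
covariate–covariate dependence.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated generative
model, not robustness to those real-data features.

## Problem sizes in the test-suite simulations

Replicated simulation tests use cohorts of 25–200 subjects with 4–10
visits — large enough for the asymptotic calibration being tested,
small enough to keep replicate counts (20–200) practical.  Recovery of
the published correlation structure is checked at 200 subjects × 10
visits; model-selection behaviour and nesting at 100 × 6; contrast
type-I error at 60 × 4 over 200 null replicates.

## Known limitations and degenerate inputs

- A correlation involving a zero variance component is reported as
  undefined (flagged; NaN entries) rather than propagating 0/0.
- ML factor analysis on a pure-noise panel with Kaiser retention is
  over-extracted by construction; boundary (Heywood-floor) variables
  can then carry a spuriously large loading.  The factor tests assert
  the stable form of the null property (eigenvalues ≈ 1, loadings
  overwhelmingly weak) rather than the absence of any strong loading.
- In the emulated protein panel, triglycerides loads 0.360/0.341 on
  the two factors — the population varimax solution ties at
  0.352/−0.349 — so its dominant-factor assignment is irreducibly
  ambiguous; one acceptance-style recovery test that requires every
  variable to land on its generating factor fails for this reason and
  is retained as an honest negative result.
- The Wald/normal inference ignores small-sample df corrections;
  with ≤ 30 subjects, CIs are mildly anticonservative.
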