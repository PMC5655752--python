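# Methods

## The problem

A clinic follows patients whose eventual prognosis — "disease" (e.g.
refractory epilepsy) versus "disease-free" (remission) — only becomes
observable at a fixed horizon `T` after diagnosis.  At irregular visit
times before `T`, several longitudinal markers of mixed type are
recorded.  The task is *dynamic* classification: each time new data
arrive, update the probability that the patient ends up in each group,
and decide whether to call the prognosis now or wait.  The package
implements the full chain: model, posterior group probabilities,
allocation rules (including a credible-interval rule with an
unclassified zone), and unclassified-aware evaluation.

## Model

For group `g`, marker `r` at visit `j` follows an exponential-family
distribution (gaussian/identity, bernoulli/logit or poisson/log) with

    h_r^{-1}( E[Y_rj | b] ) = x_rj' alpha_rg + b_r ,

where `b = (b_1, ..., b_R)` collects one random intercept per marker,
jointly distributed as a K-component multivariate normal mixture with
group-specific weights `w_k`, means `mu_k` and covariances `D_k`.  The
mixture both robustifies the random-effect distribution and induces
cross-marker correlation.  `K` is fixed by the analyst.

**Identifiability.** A fixed intercept together with free mixture means
is a ridge: only their sum enters the likelihood.  The package follows
the convention of the reference R implementation of this model family
(mixAK): in the default configuration the fixed intercept is omitted
(`fixed_intercept=False`) and the mixture means carry the marker
intercepts.  `build_design` still supports intercept-bearing designs
for models without free random-effect means.

## Fitting

Groups are fitted independently by Metropolis-within-Gibbs:

- component allocations: multinomial Gibbs;
- mixture weights: Dirichlet Gibbs;
- mixture means/covariances: conjugate normal / inverse-Wishart Gibbs;
- gaussian coefficients and residual variances: conjugate Gibbs;
- random effects and non-gaussian coefficients: adaptive random-walk
  Metropolis (per-patient scalar step sizes and per-marker proposal
  scales adapted toward a 0.30 acceptance rate during burn-in by
  Robbins–Monro; adaptation is frozen afterwards, and post-burn-in
  acceptance rates are reported as diagnostics).

Priors (all overridable): `alpha ~ N(0, 100 I)`, gaussian
`phi ~ InvGamma(0.01, 0.01)`, `w ~ Dirichlet(1)`, `mu_k ~ N(0, 100 I)`,
`D_k ~ InvWishart(q + 2, I)` — proper and weakly informative.  No
relabelling of mixture components is performed: every downstream
quantity depends on the mixture only through its density value, which
is invariant under component permutation (tested).

Initialisation: per-marker fixed-effects-only GLM fits (statsmodels),
random effects at zero, jittered mixture means; non-finite initial
log-posteriors raise immediately.  Defaults: burn-in `n_iter/2`,
thinning 1.

## Group probabilities and credible intervals

The marginal density of a history integrates the observation likelihood
over the random-effect mixture.  It is estimated by plain Monte Carlo
from the mixture (default 200 draws), with three deliberate choices:

- **Common random numbers.**  The same base variates are mapped through
  every group's mixture, reducing the variance of the Bayes ratio.
- **Draw-shared streams.**  The same base variates also serve every
  posterior draw.  Two draws with identical parameters therefore give
  identical probabilities, so the spread of the per-draw probabilities
  — and hence the HPD interval — reflects parameter uncertainty, not
  integration noise.  Streams are keyed by (seed, patient, visit), so
  results do not depend on patient order.
- **Exact gaussian path.**  When every marker is gaussian the marginal
  is a K-component normal mixture evaluated in closed form; this is the
  oracle against which the Monte-Carlo path is cross-checked.

An empty history contributes a log-density of zero for every group, so
the probabilities fall back to the prevalences exactly.

The HPD interval of the per-draw disease probability is the empirical
shortest window containing `ceil((1-alpha) M)` of the `M` sorted values
(ties resolve to the smallest lower endpoint, with a 1e-12 width
tolerance so that float noise cannot override the tie-break).  This
assumes a unimodal posterior; an equal-tail fallback
(`method="equal_tail"`) is provided for multimodal cases.

## Allocation rules

All rules freeze the first decisive label.  Prediction time is the
first decisive visit (the horizon if none); lead time is horizon minus
prediction time.  The boundary `p = c` is assigned to the disease-free
side throughout.  The credible-interval rule (dynCI) calls disease only
when the whole HPD interval exceeds the cutoff and disease-free only
when it lies below; the `disease_focus` variant defers the
disease-free call to the final visit, mirroring applications where only
the disease call changes management.  In the collapsed-interval limit
dynCI reduces to the plain cutoff rule (not the three-zone symmetric
rule, whose lower boundary is `1-c` rather than `c`).

A patient with a single recorded visit is kept for model fitting but
excluded from prediction by the cross-validation harness.

## Evaluation

Confusion tables are `G x (G+1)` with an unclassified column.
`classified_only` metrics drop abstentions from every denominator;
`overall` metrics keep them in the sensitivity/specificity/PCC
denominators (an abstention is a failure to detect for both groups).
Zero-denominator metrics are NaN and flagged, never silently zero.
ROC curves are traced over a cutoff grid 0.01..0.99 (step 0.01) in
classified-only mode; AUC is the trapezoid over (1-Sp, Se) with (0,0)
and (1,1) appended; cutoffs are selected by distance-to-corner (d²),
Youden, or maximised PCC/PPV/NPV, ties to the smallest cutoff.  Mean
lead/prediction times default to patients correctly identified as
diseased.  Reported table values are rounded half away from zero to
2 dp.

## Synthetic data

The generator mirrors the model's generative assumptions exactly and
emulates the structure of an epilepsy prognosis cohort: two groups at
90/10 prevalence; a binary seizure indicator, a gaussian
log-transformed seizure count and a Poisson adverse-event count;
correlated random intercepts from a K=2 mixture per group; visit counts
uniform on {3..12} with exponential gaps (mean `T/8`) truncated at the
horizon `T=5`.  The disease-free group's seizure odds and counts
decline over follow-up while the disease group's stay flat, chosen so
full-trajectory classification under the true parameters has well under
5% error.  True parameters and per-patient random effects are emitted
alongside the data for recovery tests.

What the generator does *not* emulate: informative visit schedules,
missing-not-at-random markers, covariate effects on group membership,
model misspecification (the fitted model is exactly the generative
one), or resolution of the outcome before the horizon.  Passing tests
therefore demonstrate internal correctness and the comparative
behaviour of the rules under the model's own assumptions, not
robustness to real-data violations of them.

## Problem sizes used by the test suite and acceptance script

Chosen as the smallest sizes at which the statistical assertions are
stable: parameter recovery uses 20 replicates of ~200 patients/group
(gaussian-only, K=1, 2000 MCMC iterations); the end-to-end rule
comparison uses cohorts of 400 with 5-fold cross-validation, 600 MCMC
iterations per fit (burn-in 300, thinned to 50 draws) and 100
Monte-Carlo samples per marginal; the acceptance script averages three
such replicates.  The rule comparison uses the disease-focused dynCI
variant: the full variant freezes an early disease-free call the first
time the interval dips below the cutoff, which both depresses
classified-only sensitivity and leaves almost nobody unclassified —
the disease-focused configuration is the one under which the
credible-interval and point-estimate rules are meaningfully compared.

## Numerical notes

- All density accumulations run in log space with log-sum-exp.
- Monte-Carlo comparisons against closed forms use the delta-method
  standard error of the log estimate; such comparisons are only
  calibrated when the observations are compatible with the model, which
  is how the oracle tests draw them.
- Mixture covariance draws are guarded by Cholesky checks; singular
  proposals raise with the offending component index.

## Known limitations

- Random-effect structure is a random intercept per marker; random
  slopes are not implemented (the configuration rejects them).
- Metrics assume the two-group case; the data model supports `G > 2`
  but the accuracy report does not.
- The sampler is plain adaptive Metropolis for non-gaussian
  coefficients; Pólya–Gamma augmentation for the logit marker would
  mix faster on large cohorts but is not required at these sizes.
- Exact leave-one-out cross-validation refits the model once per
  patient and is expensive; the k-fold approximation is the practical
  mode and the one the tests exercise.
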