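# Methods

`cohortmi` implements multiple imputation (MI) of covariates that are
missing *by design* (measured only in a substudy) or *by chance* in
prospective cohorts whose outcome model is a Cox proportional-hazards
regression, for the two standard substudy designs: nested case-control
(NCC) and case-cohort (CC). This note records the models, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Substantive model and substudy likelihoods

The hazard for covariates (x1, x2, z) is

    h(t | x1, x2, z) = h0(t) * exp(b1*x1 + b2*x2 + bz*z).

A full cohort is analysed by maximizing Cox's partial likelihood with risk
sets R_j = {k : T_k >= tau_j}. A substudy is analysed with the modified
partial likelihood in which R_j is replaced by a sampled subset: the case
plus c sampled controls (NCC) or the subcohort members at risk plus the
case if outside the subcohort (CC). For NCC this is a true partial
likelihood and the model-based variance (inverse observed information)
applies; for CC it is a pseudo-partial likelihood, and we use a robust
sandwich variance assembled from per-individual score residuals
(Lin–Ying-type: each person's summed contributions to the per-event score
terms), since the exact variance form is not prescribed by the method
itself.

Fitting is Newton–Raphson with step-halving, convergence when the score
max-norm drops below 1e-9 or the relative log-likelihood change below
1e-12, at most 50 iterations. A coefficient exceeding 20 in absolute value
aborts with an error: a monotone (separated) partial likelihood otherwise
stalls quietly at an arbitrary large value. Tied event times use the
Breslow approximation; the simulator never produces ties, but CSV input may.
Degenerate fits (a covariate constant within every risk set) fall back to a
pseudo-inverse variance with a warning rather than failing, so that the
coefficient — which is well-defined at zero — is still reported.

## Imputation methods

**Approximate method.** A partially observed covariate X is imputed from a
regression of X on the other covariates, the event indicator D, and the
cumulative hazard evaluated at the follow-up time, H(T): linear for
continuous X, logistic for binary X. Parameter uncertainty is propagated by
drawing from the approximate posterior — Normal(alpha_hat, V_hat) for
logistic models; for linear models sigma^2 from its scaled inverse
chi-square posterior, then alpha | sigma^2 from Normal(alpha_hat,
sigma^2 (X'X)^-1). With two or more incomplete covariates the univariate
models are cycled as chained equations (default 10 cycles, each model
fitted on the originally observed rows with current working fills in the
predictors); with a single target one pass is a complete draw.

**Substantive-model-compatible (SMC) method.** A proposal value is drawn
from a covariate-only model p(X | other covariates) — never conditioning on
the outcome — and accepted with probability proportional to the Cox-model
density of the observed outcome at the proposed value:

    censored:  exp(-u),          u = H0(T) * exp(linear predictor)
    event:     u * exp(1 - u),

the event rule being the valid rejection envelope obtained from
max_u u*e^-u = e^-1. Both expressions are provably in [0, 1]. Accepted
draws therefore follow p(X | T, D, rest) exactly for the current
substantive parameters; the test suite checks this against an exact
two-point enumeration for binary X. Substantive parameters (beta, H0) are
refitted and redrawn at the start of every FCS cycle — beta from
Normal(beta_hat, V_hat), H0 recomputed at the drawn beta. A cell that
exhausts `max_rejects` (default 1000) keeps its highest-acceptance draw and
is logged; a run where more than 5% of cells fall back carries a warning in
its report. Candidates are drawn in batches of 64 per cell purely for
speed; the batch is scanned in order, so the accepted draw is identical in
distribution to one-at-a-time sampling.

Because acceptance is evaluated through the substantive model's own linear
predictor, the substantive model may contain transformed terms (log,
square, interactions) of an imputed covariate, and the proposal may model
the covariate on a different scale (e.g. log X conditionally normal while X
enters the hazard linearly). This is the feature exercised by the
misspecification scenario below.

**Matched-set method (NCC only).** In the minimum information setting
(nothing known beyond the sampled sets), missing x2 is imputed within
risk sets from a logistic model whose predictors are the member's own x1
and z, the sums of x1, x2 and z over the *other* members of the same set,
and (by default, switchable) the member's case/control indicator, which is
known within every set. Co-member sums depend on imputed values, so the
model is cycled (default 10); variable set sizes are handled, with
singleton sets flagged and given zero sums. The operation takes no
cohort-level inputs whatsoever — that is the point of the method, and a
test asserts it structurally.

## Three approaches, three information settings

- **Full-cohort approach** (maximum information): impute x1 and x2 on the
  whole cohort; analyse the whole cohort by full partial likelihood.
- **Intermediate approach**: impute on the whole cohort; analyse only the
  substudy. Imputed cells outside the substudy never enter the analysis
  likelihood (asserted structurally in tests). More robust to imputation-
  model error than the full-cohort approach, more efficient than the
  substudy approach.
- **Substudy approach** (time-only or minimum information): impute and
  analyse the substudy only. The approximate method needs a cumulative-
  hazard input: the full-cohort Nelson–Aalen curve when (T, D) are known
  cohort-wide, or for CC a design-adapted estimator.

Design-adapted cumulative hazards for CC:

    H_cc(t)   = (n_S(0)/n) * sum_{tau_k <= t} d(tau_k) / n_S(tau_k)
    H_cc*(t)  =             sum_{tau_k <= t} d(tau_k) / n_cc(tau_k)

with n_S(tau) the subcohort at-risk count and n_cc(tau) = n_S(tau) plus one
if the case at tau is outside the subcohort. H_cc* is the Nelson–Aalen
estimator applied to the case-cohort sample under the usual convention that
a non-subcohort case contributes risk time only at its own event; the test
suite verifies this identity exactly against an independent delayed-entry
implementation. Note H_cc* carries the scale (n/n_S(0)) relative to H_cc:
as a regressor in the imputation model the scale is absorbed by its
coefficient, which is why the choice among the inputs is immaterial in
practice (verified as a paired property test).

Baseline cumulative hazards for SMC: the Breslow estimator (full-cohort
approach), the modified Breslow estimator over subcohort members scaled by
the known sampling fraction n_S(0)/n (CC), or the sampled-risk-set
estimator with per-set weight n(tau_k)/(c(tau_k)+1) (NCC), which needs the
full-cohort at-risk counts and is therefore a time-only-information tool.
The covariate model p(x2 | x1, z) is fitted on the subcohort (CC; a random
sample of the cohort), or for NCC on the controls (rare-disease
approximation, the default, which performed best in our experiments) or by
inverse-probability weighting with Samuelsen inclusion probabilities

    p_i = 1 - prod_{tau_j <= T_i} (1 - c(tau_j)/(n(tau_j) - 1)),

non-cases weighted 1/p_i and cases entering with weight 1 (the standard
convention; the method text leaves it open).

## Pooling and intervals

Rubin's rules: pooled estimate = mean of the M per-imputation estimates;
total variance = within + (1 + 1/M) * between; per-coefficient df
(M-1)(1 + W/((1+1/M)B))^2. MI intervals use the t distribution with that df
(normal quantiles optionally, and when B = 0); single-fit intervals use
normal quantiles.

## Synthetic-data generator

The generator emulates a prospective cohort: three correlated covariates —
x1 standard normal, x2 and z Bernoulli(0.5) — obtained from a latent
trivariate Gaussian with exchangeable correlation (default 0.5) by
thresholding at the quantiles matching the marginals; event times from the
Weibull hazard h(t) = t * lam * e^lp (lam = 1) by inverse transform,
t = sqrt(-2 log U / (lam e^lp)); fixed administrative censoring, with a
helper that calibrates the censoring time to a target event fraction by
root finding (default scenarios use 10%, the order of magnitude of large
cardiovascular cohorts); missing-at-random x2 with
P(miss | z, D) = expit(g0 + 0.5 z + 0.5 D + 0.25 zD), g0 calibrated by
scalar root finding so the population-averaged fraction hits its target
(10% or 50% in the standard scenarios). x1 is masked by design outside
whichever substudy is drawn. A misspecified variant generates log-normal x1
(log x1 ~ N(0.25 z, 0.65^2)) and x2 ~ Bernoulli(expit(0.5 z +
0.25 (x1 + x1^2))), which breaks normal/main-effects imputation models
while the substantive model keeps linear terms.

What the generator does **not** emulate: covariate-dependent censoring,
left truncation, tied event times (broken by an epsilon jitter), additional
NCC matching variables, stratified subcohort sampling, and real-data
features such as measurement error or non-proportional hazards. Passing
tests therefore demonstrate correctness of the estimators and samplers
under the stated models, not robustness to those violations.

Determinism: a scenario plus its seed reproduces a cohort bit-for-bit; a
study's base seed spawns independent streams per replicate, per method and
per imputation, so all methods within a replicate see the same cohort and
design draw (paired comparisons) and a full study re-run is bit-identical.

## Study harness and problem sizes

`run_study` repeats simulate → mask → sample design → analyse, and reports
per method and coefficient: mean estimate, bias, empirical SE, mean model
SE, coverage of nominal 95% intervals, efficiency relative to the
complete-data substudy analysis (ratio of empirical variances), and Monte
Carlo SEs for bias and coverage. Replicate failures are excluded and
counted; a study with more than 5% failures is marked invalid. The bundled
acceptance script uses 200 replicates of n = 15,000 for the complete-data
checks, 100 replicates of n = 5,000 for SMC recovery, and 100 replicates of
n = 15,000 for the misspecification scenario — sizes chosen so the whole
script completes in a few minutes on one CPU while keeping Monte Carlo
error well below the effects being measured.

## Known limitations

- The CC sandwich variance is one reasonable robust choice; finite-
  population corrections for subcohort sampling are not applied.
- The rare-disease (controls-only) covariate model carries O(event
  fraction) bias by construction; the IPW alternative removes it at some
  efficiency cost.
- The SMC event-case acceptance probability is small when H0(T) e^lp is far
  from 1 (very early events), which is where `max_rejects` fallbacks
  concentrate; the fallback slightly favours the higher-acceptance value
  for those cells.
- Rubin's variance is known to over-cover in the intermediate approach
  (imputer assumes more than the analyst); this is reported, not corrected.
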