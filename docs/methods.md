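# Methods

## The model and the closed-form estimator

`pairhr` targets 1:1 matched cohort studies with a censored time-to-event
outcome: each pair k holds one exposed (e = 1) and one unexposed (e = 0)
subject, and the working model is a Cox proportional-hazards model
stratified on pairs,

    lambda_ke(t) = lambda_k0(t) * exp(beta * e),

with an arbitrary, pair-specific baseline hazard `lambda_k0` and a common
log hazard ratio `beta`. Each subject contributes an observed time
X = min(T, U, tau) (event time, drop-out time, end of follow-up) and an
event indicator Y = 1{X = T}.

Within one pair the stratified partial likelihood depends only on *which
member fails first among those still observable*. Classifying pairs by the
order of events/censorings gives nine types (`pairhr.pair_data.PairType`);
only the "comparable" pairs — those whose shorter-observed-time member had
an event — contribute, with factor exp(beta)/(1+exp(beta)) when that member
is exposed and 1/(1+exp(beta)) when unexposed. Writing G and H for the two
counts, the partial likelihood is binomial, the maximizer is

    HR_hat = G/H,        Var(log G/H) ~ 1/G + 1/H,

the score test of beta = 0 is the stratified log-rank statistic
(G-H)^2/(G+H), and C = max(G,H)/(G+H) is the matched-pair concordance
statistic, with odds C/(1-C) = exp(|log HR_hat|). These identities are
exact, and the test suite checks them against the iterative Newton fit to
1e-8 or better.

Two auxiliary common-HR estimators for the same data are included for the
person-time view: the Mantel–Haenszel rate ratio (point estimate only; no
published variance form is adopted) and the conditional-Poisson MLE, the
root of

    sum_k (Y_k1 X_k0 - HR * Y_k0 X_k1) / (X_k0 + HR * X_k1) = 0,

solved by bracketed root finding on log HR starting from [-10, 10] with
geometric expansion (the estimating function is monotone, so the root is
unique). The two agree to first order near HR = 1; a Monte-Carlo test
checks |difference in log| < 0.02 at 2000 pairs under the null.

### Ties and conventions

* **Within-pair tied event times** (both events at the same recorded time)
  are handled with the Breslow convention: the stratum contributes
  exp(beta)/(1+exp(beta)) * 1/(1+exp(beta)), algebraically the same as one
  pair of each comparable type, so the pair adds 1 to both G and H. Efron
  or exact tie handling is not implemented; with continuous times the case
  has probability zero, and in recorded data it should reflect genuine
  ties, not rounding (times are compared exactly, never with a tolerance).
* **Event vs censoring at the same time**: the standard convention that
  censoring happens just after events, so the event holder is the
  comparable member.
* **Both censored at the same time**: type 9 when the time equals a finite
  tau (administrative end of follow-up), else type 7 with the exposed
  member listed first. This labeling convention is the one place the
  nine-way table is not exactly exposure-swap symmetric; G and H always
  swap.
* tau defaults to unbounded; type 9 can only occur when a finite tau is
  supplied.

## The Cox engine

`pairhr.coxph` is a self-contained Newton–Raphson maximizer of the Breslow
partial likelihood with optional strata, case weights and clusters. It
exists (rather than delegating to an external fitter) because the package's
central claims are *identities between the closed form and the iterative
fit*, which require full control of tie handling and variance conventions;
external fitters (statsmodels PHReg, lifelines) appear in the tests as
independent oracles only.

Numerical choices:

* Risk set at t contains subjects with time >= t; risk sums are computed by
  within-stratum suffix cumulative sums after a deterministic sort by
  (stratum, time, events-before-censorings), so a fit is order-independent.
* Newton steps with step halving (log-likelihood non-decreasing up to a
  relative float-noise slack of 1e-10·|loglik|); convergence on the
  gradient max-norm below 1e-8 scaled by sqrt(number of events) — the
  scaling keeps small problems at ~1e-8 while acknowledging accumulation
  noise in the risk-set sums of 10^5-subject cohorts, where the unscaled
  criterion can never be met in double precision; max 50 iterations.
* |beta| > 15 on the log scale raises a separation (monotone-likelihood)
  error; G = 0 or H = 0 is the closed-form counterpart.
* Model-based variance is the inverse observed information; the
  cluster-robust variance is the sandwich with score residuals summed
  within cluster before the outer product, with no small-sample
  correction (it matches lifelines' clustered `robust=True` to float
  precision in the tests).
* Weighted fits treat weights as case weights: integer weights reproduce
  row duplication exactly, and a constant weight w rescales the
  information by w without moving beta.

## The simulation design

`pairhr.simulator` generates cohorts from an exponential–normal frailty
model: gamma_k ~ N(0, frailty_sd^2), event rate
lambda0 * exp(gamma_k) * exp(beta*e) with defaults lambda0 = 1,
frailty_sd = 1, and three censoring mechanisms — none; independent
exponential with rate c in {1, 2, 4}; or pair-and-exposure-dependent
exponential with rate exp(gamma_k + alpha*e), alpha in
{log 0.25, 0, log 4}. A literal rate "gamma_k + alpha*e" is not a valid
exponential rate for normal gamma_k (it can be negative), so the
exponentiated reading is used; alpha is then exactly the log
censoring-rate ratio by exposure, matching how the scenarios are labeled.
Simulated follow-up is unbounded (tau = inf) unless a finite tau is set.

Because hazard ratios are noncollapsible, the population-averaged
("marginal") HR differs from exp(beta) even without confounding. The
marginal target is defined operationally: the unstratified Cox coefficient
in a large *uncensored* cohort (`marginal_hr_parameter`). The default size
is 2x10^5 pairs, giving a Monte-Carlo SE of about 0.0035 on the log scale —
small against every effect examined — at sub-second cost; larger sizes are
one argument away. Under beta = log 2 this evaluates to ~0.437 (vs 0.693
conditional): the attenuation produced by N(0,1) frailty.

`pairhr.simstudy` runs replicates with per-replicate RNGs derived from
(master seed, replicate index) via `numpy.random.SeedSequence`, so cells
are reproducible and order-independent. Per replicate it computes the
stratified PMLE (via the vectorized pair tabulation) and the unstratified
Cox estimate with model-based and pair-clustered robust SEs, then
summarizes bias, empirical SD (MCSE), mean estimated SE (MESE), RMSE
(sqrt(bias^2 + MCSE^2), ddof = 1 throughout), 95% Wald coverage and
rejection rates against *both* the conditional and the marginal targets.
Replicates where an estimator fails (G or H = 0, separation,
non-convergence) are dropped for that estimator and reported in
`n_failed`; with 250 pairs and the default scenarios failures are
essentially absent, but tiny cohorts show the policy in action.

What the generator does *not* emulate: covariate-driven matching (pairs are
exchangeable by construction), non-exponential baselines, informative
censoring that depends on the event time itself, and staggered entry.
Passing simulation checks therefore demonstrate estimator behavior under
proportional hazards within pairs with exchangeable frailty — not
robustness to misspecified matching or non-proportional effects.

## Propensity matching

`pairhr.psmatch` reproduces the standard cohort-construction recipe:
logistic propensity scores (statsmodels GLM/IRLS behind the package's
interface, with explicit rank-deficiency and separation errors), then
greedy nearest-neighbor caliper matching without replacement. The caliper
is 0.2 x SD of the scores in the unexposed reference group, on the
probability scale. The processing order — exposed subjects by descending
score, nearest available control, ties broken by subject id — is a
documented choice where practice varies; it affects which pairs form far
more than how many. Covariate transformations (splines, exp(-0.12*nodes)
style recodings) are the caller's responsibility.

## Packaged cohorts

Two deterministic fixtures support examples and tests without shipping
data files: `one_per_type` (nine pairs, one per type) and
`rotterdam_counts`, a **synthetic** 446-pair cohort constructed so its
pair-type counts give G = 198 and H = 135 — the sufficient statistics of
the published propensity-matched breast-cancer application — while its
times are arbitrary. Every closed-form statistic of the application is
reproduced exactly from these counts; nothing else about the real cohort
is represented.

## Known limitations

* Binary exposure and 1:1 matching only; no Efron/exact ties; no
  time-varying covariates, left truncation, or frailty-model *fitting*.
* No variance for the Mantel–Haenszel rate ratio or the
  conditional-Poisson MLE (point estimators only).
* The marginal-HR target inherits Monte-Carlo noise from its defining
  simulation; treat differences below ~0.01 as indistinguishable at the
  default size.
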