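# pairhr

Hazard-ratio estimation for **matched-pair cohort studies** with censored
time-to-event outcomes.

In a 1:1 matched cohort each pair holds one exposed and one unexposed
subject. Under a Cox model stratified on pairs,
`lambda_ke(t) = lambda_k0(t) exp(beta·e)`, all information about the common
hazard ratio `exp(beta)` collapses into two counts:

* **G** — pairs whose *exposed* member has the shorter observed time and an
  event,
* **H** — pairs whose *unexposed* member has the shorter observed time and
  an event.

The partial-ML estimate of the common HR is simply **G/H**, with
`Var(log G/H) ≈ 1/G + 1/H`; the score test of no effect is the stratified
log-rank statistic `(G−H)²/(G+H)`; and `max(G,H)/(G+H)` is the matched-pair
concordance (C-) statistic, whose odds equal the HR. `pairhr` implements
this closed form together with:

* a from-scratch Cox partial-likelihood engine (Breslow ties, strata,
  case weights, cluster-robust sandwich variance) — the unstratified
  "marginal HR" comparator and the iterative cross-check of the closed form;
* Mantel–Haenszel rate-ratio and conditional-Poisson common-HR estimators;
* an exponential–normal frailty simulator and Monte-Carlo harness for
  studying how censoring patterns bias marginal vs conditional estimators
  (hazard ratios are noncollapsible: the marginal HR is attenuated toward 1
  and, under censoring, depends on the censoring distribution);
* propensity-score caliper matching without replacement for building
  matched cohorts from covariate tables.

Audience: biostatisticians and epidemiologists analyzing matched (often
propensity-matched) cohorts, and methods researchers probing
marginal-vs-conditional HR behavior by simulation.

## Worked example

A packaged synthetic cohort reproduces, at the level of its pair counts,
a published propensity-matched breast-cancer application (446 pairs,
G = 198, H = 135):

```sh
$ pairhr estimate --fixture rotterdam_counts
stratified PMLE: HR=1.467 (95% CI 1.178-1.825); stratified log-rank=11.919 (p=0.000556); C=0.595 (exposed)
```

HR = 198/135 = 1.47: the exposed member fails first in 59.5% of comparable
pairs, and the odds of that concordance, 0.595/0.405, *are* the hazard
ratio. The same numbers from Python, plus the iterative cross-check:

```python
import pairhr

pairs, tau = pairhr.fixture_cohort("rotterdam_counts")
counts = pairhr.tabulate_pairs(pairs, tau)        # G=198, H=135
est = pairhr.common_hr_pmle(counts)               # HR 1.47 (1.18, 1.83)

fit = pairhr.fit_cox(pairhr.pairs_to_subject_rows(pairs), strata=True)
assert abs(fit.beta[0] - est.log_hr) < 1e-8       # closed form == Newton fit
```

Simulating the noncollapsibility story (the marginal HR is attenuated and
censoring-dependent even though matching removed all confounding):

```python
import math
from pairhr import Censoring, ScenarioConfig, run_scenario, marginal_hr_parameter

tp = marginal_hr_parameter(beta=math.log(2), n_large=200_000, seed=1)
print(tp.log_marginal_hr)   # ~0.437  (vs conditional log 2 = 0.693)

cfg = ScenarioConfig(n_pairs=250, beta=math.log(2),
                     censoring=Censoring("conditional", alpha=math.log(4)))
for r in run_scenario(cfg, n_reps=2000, master_seed=1,
                      true_log_marginal=tp.log_marginal_hr):
    if r.target == "conditional":
        print(f"{r.estimator:24s} bias={r.bias:+.2f} coverage={r.coverage:.1%}")
# stratified_pmle          bias=+0.01 coverage=94.3%
# unstratified_cox         bias=-0.39 coverage=23.4%
# unstratified_cox_robust  bias=-0.39 coverage=18.4%
```

With censoring four times heavier among the exposed, only the stratified
G/H estimator stays unbiased for the conditional HR; the unstratified
("marginal") estimator is pulled far off and its intervals collapse.

Other CLI commands: `pairhr classify` (pair-type table), `pairhr cox`,
`pairhr simulate`, `pairhr study --config scenario.yaml`, `pairhr match`.

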