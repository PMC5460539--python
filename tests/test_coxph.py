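"""The Cox partial-likelihood engine against independent oracles.

Oracles: a naive O(n^2) Breslow log partial likelihood with grid search,
statsmodels PHReg (Breslow ties), lifelines' clustered sandwich, and a
textbook risk-table log-rank statistic.
"""

import math

import numpy as np
import pandas as pd
import pytest

from pairhr import (
    SubjectRow,
    fit_cox,
    fit_cox_arrays,
    pairs_to_subject_rows,
    score_test_null,
    stratified_logrank,
    tabulate_pairs,
)
from pairhr.errors import NoInformationError, SeparationError, ValidationError
from .conftest import random_cohort


def naive_breslow_loglik(beta, time, event, x):
    """Independent O(n^2) evaluation of the Breslow log partial likelihood."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = sum(
                math.exp(beta * x[j]) for j in range(len(time)) if time[j] >= time[i]
            )
            ll += beta * x[i] - math.log(risk)
    return ll


def _sim_survival(n, seed, p=1):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    beta = np.linspace(0.5, -0.4, p)
    t = rng.exponential(1 / np.exp(x @ beta))
    c = rng.exponential(1.2, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event, x


def test_six_subject_fit_matches_grid_search_oracle():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 0, 1, 1, 0, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    fit = fit_cox_arrays(time, event, x)
    grid = np.arange(-5.0, 5.0, 1e-4)
    lls = np.array([naive_breslow_loglik(b, time, event, x) for b in grid])
    best = grid[np.argmax(lls)]
    assert fit.beta[0] == pytest.approx(best, abs=1e-4)
    assert fit.loglik == pytest.approx(lls.max(), abs=1e-6)


def test_identical_group_time_distributions_give_zero_beta():
    times = [1.0, 2.0, 3.0, 4.0]
    events = [1, 1, 0, 1]
    time = np.array(times * 2)
    event = np.array(events * 2)
    x = np.array([1.0] * 4 + [0.0] * 4)
    fit = fit_cox_arrays(time, event, x)
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("n,p", [(80, 1), (200, 2)])
def test_matches_statsmodels_phreg(n, p):
    from statsmodels.duration.hazard_regression import PHReg

    time, event, x = _sim_survival(n, seed=n + p)
    fit = fit_cox_arrays(time, event, x)
    ref = PHReg(time, x, status=event, ties="breslow").fit()
    np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se_model, ref.bse, rtol=1e-6)


def test_clustered_sandwich_matches_lifelines():
    from lifelines import CoxPHFitter

    time, event, x = _sim_survival(120, seed=42, p=2)
    clusters = np.repeat(np.arange(60), 2)
    fit = fit_cox_arrays(time, event, x, clusters=clusters)
    df = pd.DataFrame(
        {"T": time, "E": event, "x1": x[:, 0], "x2": x[:, 1], "g": clusters}
    )
    cf = CoxPHFitter()
    cf.fit(df, "T", "E", formula="x1+x2", robust=True, cluster_col="g")
    np.testing.assert_allclose(fit.beta, cf.params_.values, atol=1e-5)
    np.testing.assert_allclose(fit.se_robust, cf.standard_errors_.values, rtol=1e-4)


def test_pair_stratified_score_test_equals_stratified_logrank():
    for seed in range(5):
        pairs = random_cohort(60, seed=seed, beta=0.3)
        rows = pairs_to_subject_rows(pairs)
        st = score_test_null(rows, strata=True)
        lr = stratified_logrank(tabulate_pairs(pairs))
        assert st.statistic == pytest.approx(lr.statistic, abs=1e-10)


def test_unstratified_score_test_is_classical_logrank():
    """Score test at beta=0 vs a textbook risk-table log-rank statistic."""
    time, event, x = _sim_survival(100, seed=8)
    group = (x[:, 0] > 0).astype(float)
    st = score_test_null(
        [SubjectRow(i, time[i], int(event[i]), (group[i],)) for i in range(100)]
    )
    # independent risk-table construction
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n1 = group[at_risk].sum()
        ntot = at_risk.sum()
        d = int(((time == t) & (event == 1)).sum())
        o1 = int(((time == t) & (event == 1) & (group == 1)).sum())
        O += o1
        E += d * n1 / ntot
        V += d * (n1 / ntot) * (1 - n1 / ntot)  # no ties in simulated times
    assert st.statistic == pytest.approx((O - E) ** 2 / V, rel=1e-10)


def test_constant_weight_rescales_information_not_beta():
    time, event, x = _sim_survival(90, seed=17)
    base = fit_cox_arrays(time, event, x)
    w = np.full_like(time, 3.0)
    weighted = fit_cox_arrays(time, event, x, weights=w)
    assert weighted.beta[0] == pytest.approx(base.beta[0], abs=1e-8)
    assert weighted.cov_model[0, 0] == pytest.approx(base.cov_model[0, 0] / 3, rel=1e-6)


def test_integer_weights_equal_row_duplication():
    time, event, x = _sim_survival(40, seed=23)
    w = np.array([1.0, 2.0] * 20)
    weighted = fit_cox_arrays(time, event, x, weights=w)
    rep = np.repeat(np.arange(40), w.astype(int))
    dup = fit_cox_arrays(time[rep], event[rep], x[rep])
    assert weighted.beta[0] == pytest.approx(dup.beta[0], abs=1e-8)
    assert weighted.loglik == pytest.approx(dup.loglik, rel=1e-10)


def test_time_scale_invariance_of_beta():
    time, event, x = _sim_survival(70, seed=31)
    a = fit_cox_arrays(time, event, x)
    b = fit_cox_arrays(np.expm1(time / time.max()), event, x)
    assert b.beta[0] == pytest.approx(a.beta[0], abs=1e-7)


def test_gradient_small_at_solution_and_loglik_increased():
    time, event, x = _sim_survival(150, seed=3)
    fit = fit_cox_arrays(time, event, x)
    assert fit.converged
    assert fit.loglik >= fit.loglik_null


def test_separation_raises():
    # events occur in exact covariate order: monotone likelihood
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 1, 1])
    x = np.array([3.0, 2.0, 1.0, 0.0])
    with pytest.raises(SeparationError):
        fit_cox_arrays(time, event, x)


def test_no_events_raises():
    with pytest.raises(NoInformationError):
        fit_cox_arrays(np.array([1.0, 2.0]), np.array([0, 0]), np.array([1.0, 0.0]))


def test_subject_row_validation():
    with pytest.raises(ValidationError):
        fit_cox([SubjectRow("a", -1.0, 1, (1.0,))])
    with pytest.raises(ValidationError):
        fit_cox(
            [SubjectRow("a", 1.0, 1, (1.0,)), SubjectRow("b", 2.0, 0, (0.0,))],
            strata=True,
        )
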