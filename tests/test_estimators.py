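"""Closed-form estimators: worked values, boundaries, cross-estimator checks."""

import math

import numpy as np
import pytest

from pairhr import (
    PairCounts,
    PairRecord,
    common_hr_pmle,
    fit_cox,
    mcnemar_test,
    mh_rate_ratio,
    pair_c_statistic,
    pairs_to_subject_rows,
    poisson_cmle,
    stratified_logrank,
    tabulate_pairs,
)
from pairhr.errors import BoundaryError, NoInformationError
from .conftest import random_cohort


class TestCommonHRPMLE:
    def test_published_pair_counts_give_hr_1_47(self):
        est = common_hr_pmle(PairCounts(n1=198, n2=135))
        assert round(est.hr, 2) == 1.47
        assert round(est.ci_low, 2) == 1.18
        assert round(est.ci_high, 2) == 1.83
        assert est.se == pytest.approx(math.sqrt(1 / 198 + 1 / 135))

    def test_symmetric_counts_give_unit_hr(self):
        est = common_hr_pmle(PairCounts(n1=10, n2=10))
        assert est.hr == pytest.approx(1.0)
        assert est.se == pytest.approx(math.sqrt(0.2))

    def test_boundaries(self):
        with pytest.raises(BoundaryError) as exc:
            common_hr_pmle(PairCounts(n1=5))
        assert exc.value.direction == "+inf"
        with pytest.raises(BoundaryError) as exc:
            common_hr_pmle(PairCounts(n2=5))
        assert exc.value.direction == "-inf"
        with pytest.raises(NoInformationError):
            common_hr_pmle(PairCounts())

    def test_matches_iterative_stratified_partial_likelihood(self):
        """Closed form == Newton-Raphson maximizer of the stratified PL."""
        pairs = random_cohort(200, seed=3, beta=0.7)
        counts = tabulate_pairs(pairs)
        est = common_hr_pmle(counts)
        fit = fit_cox(pairs_to_subject_rows(pairs), strata=True)
        assert fit.beta[0] == pytest.approx(est.log_hr, abs=1e-8)
        assert fit.cov_model[0, 0] == pytest.approx(est.se**2, rel=1e-8)


class TestStratifiedLogrank:
    def test_null_symmetry(self):
        t = stratified_logrank(PairCounts(n1=50, n2=50))
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_published_counts(self):
        t = stratified_logrank(PairCounts(n1=198, n2=135))
        assert t.statistic == pytest.approx(63**2 / 333)
        assert t.statistic == pytest.approx(11.92, abs=0.005)

    def test_no_comparable_pairs(self):
        with pytest.raises(NoInformationError):
            stratified_logrank(PairCounts(n5=3))


class TestPairCStatistic:
    def test_published_counts(self):
        c = pair_c_statistic(PairCounts(n1=198, n2=135))
        assert c.c == pytest.approx(198 / 333)
        assert c.odds == pytest.approx(198 / 135)
        assert c.direction == "exposed"

    def test_balanced_counts_give_half(self):
        c = pair_c_statistic(PairCounts(n1=7, n2=7))
        assert c.c == 0.5 and c.direction == "tie"

    def test_swap_preserves_c_flips_direction(self):
        a = pair_c_statistic(PairCounts(n1=30, n2=10))
        b = pair_c_statistic(PairCounts(n1=10, n2=30))
        assert a.c == b.c and {a.direction, b.direction} == {"exposed", "unexposed"}

    def test_odds_identity_with_pmle(self):
        pairs = random_cohort(150, seed=9, beta=-0.4)
        counts = tabulate_pairs(pairs)
        c = pair_c_statistic(counts)
        est = common_hr_pmle(counts)
        assert c.odds == pytest.approx(math.exp(abs(est.log_hr)))


class TestMHRateRatio:
    def test_hand_evaluated_single_pair(self):
        est = mh_rate_ratio([PairRecord("k", 1.0, 1, 2.0, 1)])
        assert est.hr == pytest.approx(2.0)
        assert est.se is None and est.ci_low is None

    def test_no_events_is_no_information(self):
        with pytest.raises(NoInformationError):
            mh_rate_ratio([PairRecord("k", 1.0, 0, 2.0, 0)])

    def test_one_sided_events_hit_boundaries(self):
        with pytest.raises(BoundaryError):
            mh_rate_ratio([PairRecord("k", 1.0, 1, 2.0, 0)])
        with pytest.raises(BoundaryError):
            mh_rate_ratio([PairRecord("k", 1.0, 0, 2.0, 1)])


class TestPoissonCMLE:
    def test_balanced_pair_gives_unit_hr(self):
        est = poisson_cmle([PairRecord("k", 1.0, 1, 1.0, 1)])
        assert est.hr == pytest.approx(1.0, abs=1e-9)

    def test_no_unexposed_events_diverges(self):
        with pytest.raises(BoundaryError):
            poisson_cmle([PairRecord("k", 1.0, 1, 2.0, 0)] * 1)

    def test_root_matches_grid_sign_change(self):
        """Root of the estimating equation vs a fine bracketing grid."""
        pairs = random_cohort(150, seed=21, beta=0.4)
        est = poisson_cmle(pairs)
        x1 = np.array([p.x1 for p in pairs]); y1 = np.array([p.y1 for p in pairs])
        x0 = np.array([p.x0 for p in pairs]); y0 = np.array([p.y0 for p in pairs])

        def g(theta):
            hr = np.exp(theta)
            return np.sum((y1 * x0 - hr * y0 * x1) / (x0 + hr * x1))

        grid = np.linspace(est.log_hr - 0.1, est.log_hr + 0.1, 20001)  # step 1e-5
        vals = np.array([g(t) for t in grid])
        sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
        assert len(sign_change) == 1
        lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
        assert lo - 1e-8 <= est.log_hr <= hi + 1e-8

    def test_agrees_with_mh_near_null(self):
        """The MH rate ratio is a first-order approximation at HR = 1."""
        pairs = random_cohort(2000, seed=5, beta=0.0)
        a = poisson_cmle(pairs)
        b = mh_rate_ratio(pairs)
        assert abs(a.log_hr - b.log_hr) < 0.02


@pytest.mark.parametrize("beta", [0.6, -0.8])
def test_exposure_swap_antisymmetry_of_all_estimators(beta):
    pairs = random_cohort(300, seed=13, beta=beta)
    swapped = [p.swapped() for p in pairs]
    c, cs = tabulate_pairs(pairs), tabulate_pairs(swapped)
    assert common_hr_pmle(cs).log_hr == pytest.approx(-common_hr_pmle(c).log_hr)
    assert stratified_logrank(cs).statistic == pytest.approx(
        stratified_logrank(c).statistic
    )
    assert pair_c_statistic(cs).c == pytest.approx(pair_c_statistic(c).c)
    assert mh_rate_ratio(swapped).log_hr == pytest.approx(-mh_rate_ratio(pairs).log_hr)
    assert poisson_cmle(swapped).log_hr == pytest.approx(
        -poisson_cmle(pairs).log_hr, abs=1e-7
    )


def test_mcnemar_uses_event_indicators_only():
    pairs = [
        PairRecord("a", 1.0, 1, 2.0, 0),  # B
        PairRecord("b", 5.0, 1, 2.0, 0),  # B (times ignored)
        PairRecord("c", 1.0, 0, 2.0, 1),  # C
        PairRecord("d", 1.0, 1, 2.0, 1),  # concordant, ignored
    ]
    t = mcnemar_test(pairs)
    assert t.statistic == pytest.approx((2 - 1) ** 2 / 3)
    with pytest.raises(NoInformationError):
        mcnemar_test([PairRecord("d", 1.0, 1, 2.0, 1)])
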