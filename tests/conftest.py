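import math

import pytest

from pairhr import (
    Censoring,
    ScenarioConfig,
    draw_cohort,
    fixture_cohort,
    marginal_hr_parameter,
    tabulate_pairs,
)


def random_cohort(n_pairs, seed, beta=0.5, censoring=Censoring("independent", rate=1.0)):
    """A generic simulated matched cohort for oracle-based tests."""
    cfg = ScenarioConfig(n_pairs=n_pairs, beta=beta, censoring=censoring, seed=seed)
    return draw_cohort(cfg)


@pytest.fixture(scope="session")
def rotterdam():
    """Packaged synthetic cohort matching the published pair counts."""
    pairs, tau = fixture_cohort("rotterdam_counts")
    return pairs, tau, tabulate_pairs(pairs, tau)


@pytest.fixture(scope="session")
def one_per_type():
    pairs, tau = fixture_cohort("one_per_type")
    return pairs, tau


@pytest.fixture(scope="session")
def marginal_truth_log2():
    """Marginal log-HR target under beta = log 2, N(0,1) frailty, lambda0=1.

    Computed once per session at 2e5 uncensored pairs (MC SE ~ 0.0035);
    shared by the simulation-table checks.
    """
    return marginal_hr_parameter(math.log(2.0), n_large=200_000, seed=314159)
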