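"""Closed-form common hazard-ratio inference for matched-pair cohorts.

Under a Cox model stratified on matched pairs with binary exposure,

    lambda_ke(t) = lambda_k0(t) * exp(beta * e),

the partial likelihood collapses to a binomial form in the two comparable-
pair counts (G, H), so the partial-ML estimate of the common HR is simply
G/H with Var(log G/H) ~ 1/G + 1/H.  The same counts give the score test of
beta = 0 — a stratified log-rank statistic (G-H)^2/(G+H) — and the matched-
pair concordance statistic C = max(G,H)/(G+H), whose odds equal the HR.

Two auxiliary common-HR estimators for the person-time view of the same
data are included: the Mantel–Haenszel rate ratio and the conditional-
Poisson maximum-likelihood estimate (root of an estimating equation in the
observed times), which agree with each other near HR = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import BoundaryError, ConvergenceError, NoInformationError
from .pair_data import PairCounts, PairRecord

__all__ = [
    "HREstimate",
    "TestResult",
    "CStatistic",
    "common_hr_pmle",
    "stratified_logrank",
    "pair_c_statistic",
    "mh_rate_ratio",
    "poisson_cmle",
    "mcnemar_test",
]


@dataclass(frozen=True)
class HREstimate:
    """A hazard-ratio estimate on the log scale with Wald interval.

    ``se``/``ci_low``/``ci_high`` are ``None`` for point-estimate-only
    methods (the Mantel–Haenszel rate ratio carries no variance formula).
    """

    log_hr: float
    se: Optional[float]
    alpha: float = 0.05
    method: str = ""

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    @property
    def ci_low(self) -> Optional[float]:
        if self.se is None:
            return None
        z = stats.norm.ppf(1 - self.alpha / 2)
        return math.exp(self.log_hr - z * self.se)

    @property
    def ci_high(self) -> Optional[float]:
        if self.se is None:
            return None
        z = stats.norm.ppf(1 - self.alpha / 2)
        return math.exp(self.log_hr + z * self.se)

    def summary(self) -> str:
        if self.se is None:
            return f"{self.method}: HR = {self.hr:.4g} (no variance estimator)"
        return (
            f"{self.method}: HR = {self.hr:.4g} "
            f"({100 * (1 - self.alpha):.0f}% CI {self.ci_low:.4g}-{self.ci_high:.4g}), "
            f"log HR = {self.log_hr:.4g} (SE {self.se:.4g})"
        )


@dataclass(frozen=True)
class TestResult:
    """A one-degree-of-freedom chi-squared test."""

    statistic: float
    name: str
    df: int = 1

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.statistic, self.df))


@dataclass(frozen=True)
class CStatistic:
    """Matched-pair concordance for censored time-to-event data.

    ``c`` is the probability, among comparable pairs, that the member of the
    higher-hazard arm fails first; ``direction`` names that arm.  The odds
    c/(1-c) equal exp(|log HR|) of the common-HR estimate exactly.
    """

    c: float
    direction: str  # "exposed", "unexposed" or "tie"

    @property
    def odds(self) -> float:
        return self.c / (1.0 - self.c) if self.c < 1.0 else math.inf


def common_hr_pmle(counts: PairCounts, alpha: float = 0.05) -> HREstimate:
    """Closed-form partial-ML estimate of the common HR: G/H.

    The Wald interval is exp(log(G/H) ± z·sqrt(1/G + 1/H)).  Raises
    :class:`BoundaryError` when G or H is zero (the estimate diverges) and
    :class:`NoInformationError` when both are.
    """
    G, H = counts.G, counts.H
    if G == 0 and H == 0:
        raise NoInformationError("no comparable pairs: G = H = 0")
    if H == 0:
        raise BoundaryError(
            f"H = 0 with G = {G}: common-HR estimate diverges to +inf",
            direction="+inf",
        )
    if G == 0:
        raise BoundaryError(
            f"G = 0 with H = {H}: common-HR estimate is 0 (log diverges to -inf)",
            direction="-inf",
        )
    return HREstimate(
        log_hr=math.log(G / H),
        se=math.sqrt(1.0 / G + 1.0 / H),
        alpha=alpha,
        method="stratified PMLE (G/H)",
    )


def stratified_logrank(counts: PairCounts) -> TestResult:
    """Stratified log-rank test of no exposure effect: (G-H)^2/(G+H).

    Identical to the score test of beta = 0 from the pair-stratified Cox
    partial likelihood; chi-squared with 1 df under the null.
    """
    G, H = counts.G, counts.H
    if G + H == 0:
        raise NoInformationError("no comparable pairs: stratified log-rank undefined")
    return TestResult(
        statistic=(G - H) ** 2 / (G + H),
        name="stratified log-rank",
    )


def pair_c_statistic(counts: PairCounts) -> CStatistic:
    """Matched-pair C-statistic max(G, H)/(G + H)."""
    G, H = counts.G, counts.H
    if G + H == 0:
        raise NoInformationError("no comparable pairs: C-statistic undefined")
    if G == H:
        return CStatistic(c=0.5, direction="tie")
    direction = "exposed" if G > H else "unexposed"
    return CStatistic(c=max(G, H) / (G + H), direction=direction)


def _pair_arrays(pairs: Sequence[PairRecord]):
    x1 = np.array([p.x1 for p in pairs], dtype=float)
    y1 = np.array([p.y1 for p in pairs], dtype=float)
    x0 = np.array([p.x0 for p in pairs], dtype=float)
    y0 = np.array([p.y0 for p in pairs], dtype=float)
    return x1, y1, x0, y0


def mh_rate_ratio(pairs: Sequence[PairRecord]) -> HREstimate:
    """Mantel–Haenszel rate-ratio estimate of the common HR.

    HR = [sum_k Y_k1 X_k0/(X_k0+X_k1)] / [sum_k Y_k0 X_k1/(X_k0+X_k1)].
    Point estimate only: no variance estimator is attached.
    """
    if len(pairs) == 0:
        raise NoInformationError("empty cohort")
    x1, y1, x0, y0 = _pair_arrays(pairs)
    tot = x0 + x1
    num = float(np.sum(y1 * x0 / tot))
    den = float(np.sum(y0 * x1 / tot))
    if num == 0.0 and den == 0.0:
        raise NoInformationError("no events in any pair: rate ratio undefined")
    if den == 0.0:
        raise BoundaryError(
            "no unexposed events: Mantel-Haenszel rate ratio diverges",
            direction="+inf",
        )
    if num == 0.0:
        raise BoundaryError(
            "no exposed events: Mantel-Haenszel rate ratio is 0",
            direction="-inf",
        )
    return HREstimate(
        log_hr=math.log(num / den),
        se=None,
        method="Mantel-Haenszel rate ratio",
    )


def poisson_cmle(pairs: Sequence[PairRecord], xtol: float = 1e-10) -> HREstimate:
    """Conditional-Poisson ML estimate of the common HR.

    Solves sum_k (Y_k1 X_k0 - HR * Y_k0 X_k1)/(X_k0 + HR * X_k1) = 0 for HR
    by bracketed root finding on log HR.  The estimating function is
    strictly decreasing in HR wherever some pair has an event, so the root
    is unique.  Point estimate only.
    """
    if len(pairs) == 0:
        raise NoInformationError("empty cohort")
    x1, y1, x0, y0 = _pair_arrays(pairs)
    if not np.any(y1 == 1):
        raise BoundaryError("no exposed events: conditional-Poisson estimate is 0",
                            direction="-inf")
    if not np.any(y0 == 1):
        raise BoundaryError("no unexposed events: conditional-Poisson estimate diverges",
                            direction="+inf")

    def g(theta: float) -> float:
        hr = math.exp(theta)
        return float(np.sum((y1 * x0 - hr * y0 * x1) / (x0 + hr * x1)))

    lo, hi = -10.0, 10.0
    for _ in range(8):  # expand bracket if the root lies outside
        if g(lo) > 0 and g(hi) < 0:
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise ConvergenceError(
            "could not bracket the conditional-Poisson estimating equation root"
        )
    theta = optimize.brentq(g, lo, hi, xtol=xtol)
    return HREstimate(log_hr=float(theta), se=None, method="conditional Poisson CMLE")


def mcnemar_test(pairs: Iterable[PairRecord]) -> TestResult:
    """McNemar's test on event indicators alone (binary-outcome analogue).

    Censoring and follow-up times are ignored: B counts exposed-only-event
    pairs, C unexposed-only-event pairs, and the statistic is (B-C)^2/(B+C).
    Use :func:`stratified_logrank` for censored time-to-event data.
    """
    B = C = 0
    for p in pairs:
        p.validate()
        if p.y1 == 1 and p.y0 == 0:
            B += 1
        elif p.y1 == 0 and p.y0 == 1:
            C += 1
    if B + C == 0:
        raise NoInformationError("no discordant pairs: McNemar's test undefined")
    return TestResult(statistic=(B - C) ** 2 / (B + C), name="McNemar")
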