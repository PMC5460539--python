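"""Cox proportional-hazards partial-likelihood engine.

A from-scratch Newton–Raphson maximizer of the Breslow partial likelihood
supporting strata, case weights and a cluster-robust sandwich variance.
It serves two roles: the unstratified comparator (marginal-HR estimator,
with or without the sandwich) and, fitted with one stratum per matched
pair, the iterative counterpart of the closed form in
:mod:`pairhr.estimators` — on pair-stratified binary-exposure data the
maximizer equals log(G/H) and the inverse information equals 1/G + 1/H.

Conventions: the risk set at an event time t contains subjects with
observed time >= t; tied event times are handled with the Breslow
approximation (every tied event sees the full risk set); events precede
censorings at equal times only in the deterministic sort, which does not
affect the Breslow likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConvergenceError,
    NoInformationError,
    RankError,
    SeparationError,
    ValidationError,
)
from .estimators import TestResult

__all__ = ["SubjectRow", "CoxFit", "fit_cox", "fit_cox_arrays", "score_test_null"]

_SEPARATION_BOUND = 15.0  # |beta| beyond this on the log scale => monotone likelihood


@dataclass(frozen=True)
class SubjectRow:
    """One subject in long format.

    ``covariates`` is the regression design for this subject (for a matched
    cohort typically the single exposure indicator); ``cluster_id`` groups
    subjects for the sandwich variance (the pair); ``stratum`` defines
    separate baseline hazards (also typically the pair).
    """

    subject_id: object
    time: float
    event: int
    covariates: tuple
    cluster_id: object = None
    stratum: object = None
    weight: float = 1.0

    def validate(self) -> None:
        if not self.time > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: time must be positive"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id!r}: event must be 0 or 1"
            )
        if not self.weight > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: weight must be positive"
            )


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit."""

    beta: np.ndarray
    cov_model: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool
    score_at_null: np.ndarray
    info_at_null: np.ndarray
    n: int
    n_events: int
    cov_robust: Optional[np.ndarray] = None
    names: Sequence[str] = field(default_factory=list)

    @property
    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model))

    @property
    def se_robust(self) -> Optional[np.ndarray]:
        if self.cov_robust is None:
            return None
        return np.sqrt(np.diag(self.cov_robust))


def _prepare(time, event, X, weights, strata):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = time.shape[0]
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
    if strata is None:
        scodes = np.zeros(n, dtype=np.int64)
    else:
        _, scodes = np.unique(np.asarray(strata), return_inverse=True)
    if np.any(time <= 0):
        raise ValidationError("all follow-up times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event indicators must be 0 or 1")
    if np.any(weights <= 0):
        raise ValidationError("weights must be positive")
    if event.sum() == 0:
        raise NoInformationError("no events: partial likelihood is flat")
    # deterministic order: stratum, then time, events before censorings
    order = np.lexsort((-event, time, scodes))
    return time[order], event[order], X[order], weights[order], scodes[order], order


def _risk_structure(time, scodes):
    """Group/stratum bookkeeping on sorted data.

    Returns (first, last, strat_start, strat_end) where ``first``/``last``
    are per-row indices of the first/last row sharing (stratum, time) and
    ``strat_start``/``strat_end`` the per-row stratum boundaries.
    """
    n = time.shape[0]
    idx = np.arange(n)
    new_strat = np.empty(n, dtype=bool)
    new_strat[0] = True
    new_strat[1:] = scodes[1:] != scodes[:-1]
    new_group = new_strat.copy()
    new_group[1:] |= time[1:] != time[:-1]
    first = np.maximum.accumulate(np.where(new_group, idx, 0))
    # last index of each (stratum, time) group: nearest group-end at or after i
    end_group = np.empty(n, dtype=bool)
    end_group[:-1] = new_group[1:]
    end_group[-1] = True
    last = np.flip(np.minimum.accumulate(np.flip(np.where(end_group, idx, n))))
    strat_start = np.maximum.accumulate(np.where(new_strat, idx, 0))
    end_strat = np.empty(n, dtype=bool)
    end_strat[:-1] = new_strat[1:]
    end_strat[-1] = True
    strat_end = np.flip(np.minimum.accumulate(np.flip(np.where(end_strat, idx, n))))
    return first, last, strat_start, strat_end


def _suffix_within(vals, strat_end):
    """Suffix sums restricted to each stratum (vals may be (n,) or (n,p...))."""
    rev = np.flip(np.cumsum(np.flip(vals, axis=0), axis=0), axis=0)
    n = vals.shape[0]
    after = np.zeros_like(rev)
    nxt = strat_end + 1
    in_range = nxt < n
    after[in_range] = rev[nxt[in_range]]
    return rev - after


def _prefix_within(vals, strat_start):
    """Prefix (inclusive) sums restricted to each stratum."""
    cum = np.cumsum(vals, axis=0)
    before = np.zeros_like(cum)
    prev = strat_start - 1
    in_range = prev >= 0
    before[in_range] = cum[prev[in_range]]
    return cum - before


class _BreslowCore:
    """Loglik/score/information of the Breslow partial likelihood."""

    def __init__(self, time, event, X, weights, scodes):
        self.time, self.event, self.X, self.w, self.scodes = (
            time, event, X, weights, scodes,
        )
        self.n, self.p = X.shape
        self.first, self.last, self.strat_start, self.strat_end = _risk_structure(
            time, scodes
        )
        self.ev = event == 1
        self.wev = weights * event

    def risk_sums(self, beta):
        eta = self.X @ beta
        eta = np.clip(eta, -500, 500)
        r = self.w * np.exp(eta)
        s0 = _suffix_within(r, self.strat_end)[self.first]
        s1 = _suffix_within(r[:, None] * self.X, self.strat_end)[self.first]
        xo = self.X[:, :, None] * self.X[:, None, :]
        s2 = _suffix_within(r[:, None, None] * xo, self.strat_end)[self.first]
        return eta, r, s0, s1, s2

    def loglik(self, beta):
        eta, _, s0, _, _ = self.risk_sums(beta)
        return float(np.sum(self.wev * (eta - np.log(s0))))

    def derivatives(self, beta):
        eta, r, s0, s1, s2 = self.risk_sums(beta)
        m = s1 / s0[:, None]
        ll = float(np.sum(self.wev * (eta - np.log(s0))))
        grad = (self.wev[:, None] * (self.X - m)).sum(axis=0)
        v = s2 / s0[:, None, None] - m[:, :, None] * m[:, None, :]
        info = (self.wev[:, None, None] * v).sum(axis=0)
        return ll, grad, info

    def score_residuals(self, beta):
        """Per-subject score residuals (sum over a cluster = its score).

        r_i = delta_i (x_i - xbar(t_i))
              - exp(eta_i) * [x_i * A(t_i) - B(t_i)],
        with A, B cumulative Breslow-hazard sums over event times <= t_i in
        the subject's stratum; weights enter through the hazard increments
        and the caller multiplies residuals by w_i.
        """
        eta, r, s0, s1, s2 = self.risk_sums(beta)
        m = s1 / s0[:, None]
        h = self.wev / s0  # hazard increment contributed by each event row
        A = _prefix_within(h, self.strat_start)[self.last]
        B = _prefix_within(h[:, None] * m, self.strat_start)[self.last]
        expeta = np.exp(np.clip(eta, -500, 500))
        resid = (
            self.event[:, None] * (self.X - m)
            - expeta[:, None] * (self.X * A[:, None] - B)
        )
        return resid


def fit_cox_arrays(
    time,
    event,
    X,
    *,
    weights=None,
    strata=None,
    clusters=None,
    tol: float = 1e-8,
    max_iter: int = 50,
    names: Sequence[str] = (),
) -> CoxFit:
    """Fit the Breslow partial likelihood by Newton–Raphson on plain arrays.

    ``strata`` and ``clusters`` are label arrays (or ``None``); the sandwich
    variance is computed when ``clusters`` is given, by summing score
    residuals within cluster before the outer-product aggregation, without
    small-sample correction.

    Convergence is on the gradient max-norm; the tolerance is scaled by
    sqrt(number of events) so that floating-point accumulation noise in the
    risk-set sums of very large cohorts does not mask an otherwise converged
    solution.
    """
    time_s, event_s, X_s, w_s, scodes_s, order = _prepare(
        time, event, X, weights, strata
    )
    core = _BreslowCore(time_s, event_s, X_s, w_s, scodes_s)
    p = core.p
    tol = tol * max(1.0, float(np.sqrt(event_s.sum())))

    beta = np.zeros(p)
    ll, grad, info = core.derivatives(beta)
    score0, info0, ll0 = grad.copy(), info.copy(), ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RankError(
                "singular information matrix (constant covariate within "
                "contributing risk sets?)"
            ) from exc
        # step halving keeps the log-likelihood non-decreasing
        alpha_step = 1.0
        ll_slack = 1e-10 * (abs(ll) + 1.0)  # float noise in large risk-set sums
        for _ in range(30):
            cand = beta + alpha_step * step
            ll_new = core.loglik(cand)
            if ll_new >= ll - ll_slack:
                break
            alpha_step /= 2.0
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood",
                                   last_iterate=beta)
        beta = cand
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            raise SeparationError(
                f"coefficient diverging (|beta| > {_SEPARATION_BOUND}): "
                "monotone partial likelihood"
            )
        ll, grad, info = core.derivatives(beta)
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(gradient max-norm {np.max(np.abs(grad)):.3g})",
            last_iterate=beta,
        )

    try:
        cov_model = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RankError("singular information at the maximum") from exc

    cov_robust = None
    if clusters is not None:
        cl = np.asarray(clusters)[order]
        resid = core.score_residuals(beta) * w_s[:, None]
        _, codes = np.unique(cl, return_inverse=True)
        nclust = codes.max() + 1
        U = np.zeros((nclust, p))
        np.add.at(U, codes, resid)
        meat = U.T @ U
        cov_robust = cov_model @ meat @ cov_model

    return CoxFit(
        beta=beta,
        cov_model=cov_model,
        loglik=ll,
        loglik_null=ll0,
        iterations=it,
        converged=converged,
        score_at_null=score0,
        info_at_null=info0,
        n=core.n,
        n_events=int(event_s.sum()),
        cov_robust=cov_robust,
        names=list(names),
    )


def _rows_to_arrays(rows: Sequence[SubjectRow], use_weights: bool):
    for r in rows:
        r.validate()
    time = np.array([r.time for r in rows], dtype=float)
    event = np.array([r.event for r in rows], dtype=int)
    X = np.array([r.covariates for r in rows], dtype=float)
    weights = (
        np.array([r.weight for r in rows], dtype=float) if use_weights else None
    )
    return time, event, X, weights


def fit_cox(
    rows: Sequence[SubjectRow],
    *,
    strata: bool = False,
    cluster: bool = False,
    use_weights: bool = False,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox model to :class:`SubjectRow` records.

    ``strata=True`` stratifies on ``SubjectRow.stratum`` (one baseline
    hazard per stratum); ``cluster=True`` adds the cluster-robust sandwich
    variance over ``SubjectRow.cluster_id``; ``use_weights=True`` applies
    the per-row case weights.
    """
    if len(rows) == 0:
        raise ValidationError("empty input")
    time, event, X, weights = _rows_to_arrays(rows, use_weights)
    strata_arr = np.array([r.stratum for r in rows], dtype=object) if strata else None
    clusters = np.array([r.cluster_id for r in rows], dtype=object) if cluster else None
    if strata_arr is not None and any(s is None for s in strata_arr):
        raise ValidationError("strata requested but some rows lack a stratum")
    if clusters is not None and any(c is None for c in clusters):
        raise ValidationError("cluster requested but some rows lack a cluster_id")
    return fit_cox_arrays(
        time, event, X,
        weights=weights, strata=strata_arr, clusters=clusters,
        tol=tol, max_iter=max_iter,
    )


def score_test_null(
    rows: Sequence[SubjectRow],
    *,
    strata: bool = False,
    use_weights: bool = False,
) -> TestResult:
    """Score test of beta = 0 from the (possibly stratified) partial likelihood.

    statistic = U(0)' I(0)^{-1} U(0).  On pair-stratified binary-exposure
    data this equals the stratified log-rank statistic (G-H)^2/(G+H)
    exactly; unstratified on two groups it is the classical log-rank test.
    """
    if len(rows) == 0:
        raise ValidationError("empty input")
    time, event, X, weights = _rows_to_arrays(rows, use_weights)
    strata_arr = np.array([r.stratum for r in rows], dtype=object) if strata else None
    time_s, event_s, X_s, w_s, scodes_s, _ = _prepare(time, event, X, weights, strata_arr)
    core = _BreslowCore(time_s, event_s, X_s, w_s, scodes_s)
    _, score, info = core.derivatives(np.zeros(core.p))
    try:
        stat = float(score @ np.linalg.solve(info, score))
    except np.linalg.LinAlgError as exc:
        raise RankError("singular information at beta = 0") from exc
    name = "stratified log-rank (score test)" if strata else "log-rank (score test)"
    return TestResult(statistic=stat, name=name)


def subject_rows_from_frame(
    df: pd.DataFrame,
    covariates: Sequence[str],
    *,
    id_col: str = "subject_id",
    time_col: str = "time",
    event_col: str = "event",
    stratum_col: Optional[str] = None,
    cluster_col: Optional[str] = None,
    weight_col: Optional[str] = None,
) -> list[SubjectRow]:
    """Build :class:`SubjectRow` records from a tidy data frame."""
    missing = [c for c in (time_col, event_col, *covariates) if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        d = rec._asdict()
        rows.append(
            SubjectRow(
                subject_id=d.get(id_col, i),
                time=float(d[time_col]),
                event=int(d[event_col]),
                covariates=tuple(float(d[c]) for c in covariates),
                stratum=d[stratum_col] if stratum_col else None,
                cluster_id=d[cluster_col] if cluster_col else None,
                weight=float(d[weight_col]) if weight_col else 1.0,
            )
        )
    return rows
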