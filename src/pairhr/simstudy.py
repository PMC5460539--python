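"""Monte-Carlo harness for comparing common- and marginal-HR estimators.

For each replicate a matched cohort is drawn from the frailty model, three
estimators are applied —

* ``stratified_pmle``   — log(G/H) with SE sqrt(1/G + 1/H),
* ``unstratified_cox``  — unstratified Cox coefficient, model-based SE,
* ``unstratified_cox_robust`` — same coefficient, pair-clustered sandwich SE

— and the estimates are summarized against *both* target parameters: the
conditional log HR (beta of the generating model) and the marginal log HR
(the censoring-free large-sample unstratified coefficient).  Reported
metrics per (estimator, target): bias, empirical SD of the estimates
(MCSE), mean estimated SE (MESE), RMSE, coverage of nominal 95% Wald
intervals, and Wald rejection rate of the null (plus the stratified
log-rank rejection rate for the stratified estimator).
"""

from __future__ import annotations

import logging
import math
import time as _time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, NumericalError
from .pair_data import tabulate_arrays
from .coxph import fit_cox_arrays
from .simulator import Censoring, ScenarioConfig, _draw_arrays, marginal_hr_parameter

__all__ = [
    "MetricsRow",
    "summarize_estimates",
    "run_scenario",
    "replicate_table",
    "ALL_ESTIMATORS",
]

logger = logging.getLogger(__name__)

ALL_ESTIMATORS = ("stratified_pmle", "unstratified_cox", "unstratified_cox_robust")


@dataclass(frozen=True)
class MetricsRow:
    """Summary of one estimator against one target over the replicates.

    Invariant: rmse^2 = bias^2 + mcse^2 on the same replicate set (with
    the empirical variance computed with ddof=1).
    """

    estimator: str
    target: str  # "conditional" or "marginal"
    true_value: float
    bias: float
    mcse: float
    mese: float
    rmse: float
    coverage: float
    rejection_rate: float
    n_reps_used: int
    n_failed: int
    logrank_rejection_rate: Optional[float] = None

    @property
    def bias_mc_se(self) -> float:
        """Monte-Carlo standard error of the reported bias."""
        return self.mcse / math.sqrt(self.n_reps_used)


def summarize_estimates(estimates, ses, truth: float, alpha: float = 0.05) -> dict:
    """Performance metrics of a vector of estimates against a true value.

    Returns bias, mcse (empirical SD, ddof=1), mese, rmse
    (sqrt(bias^2 + mcse^2)), coverage of the nominal Wald interval, and the
    Wald rejection rate of the null.
    """
    est_vec = np.asarray(estimates, dtype=float)
    se_vec = np.asarray(ses, dtype=float)
    if est_vec.shape != se_vec.shape or est_vec.ndim != 1 or len(est_vec) < 2:
        raise ConfigError("need matching 1-d vectors of length >= 2")
    z = stats.norm.ppf(1 - alpha / 2)
    bias = float(np.mean(est_vec) - truth)
    mcse = float(np.std(est_vec, ddof=1))
    return {
        "bias": bias,
        "mcse": mcse,
        "mese": float(np.mean(se_vec)),
        "rmse": math.sqrt(bias**2 + mcse**2),
        "coverage": float(np.mean(np.abs(est_vec - truth) <= z * se_vec)),
        "rejection_rate": float(np.mean(np.abs(est_vec / se_vec) > z)),
    }


def replicate_seed(master_seed: int, rep: int) -> int:
    """Deterministic child seed below 2^31 for replicate ``rep``."""
    ss = np.random.SeedSequence((int(master_seed), int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


def _one_replicate(cfg: ScenarioConfig, rep_seed: int, estimators, alpha, z):
    """Returns {estimator: (log_hr, se) or None}, plus log-rank rejection."""
    rng = np.random.default_rng(rep_seed)
    x1, y1, x0, y0 = _draw_arrays(cfg, rng)
    out = {}
    logrank_reject = None
    if "stratified_pmle" in estimators:
        counts = tabulate_arrays(x1, y1, x0, y0, cfg.tau)
        G, H = counts.G, counts.H
        if G == 0 or H == 0:
            out["stratified_pmle"] = None
        else:
            out["stratified_pmle"] = (math.log(G / H), math.sqrt(1 / G + 1 / H))
        if G + H > 0:
            logrank_stat = (G - H) ** 2 / (G + H)
            logrank_reject = logrank_stat > stats.chi2.ppf(1 - alpha, 1)
    need_cox = {"unstratified_cox", "unstratified_cox_robust"} & set(estimators)
    if need_cox:
        n = cfg.n_pairs
        time = np.concatenate([x1, x0])
        event = np.concatenate([y1, y0])
        X = np.concatenate([np.ones(n), np.zeros(n)])
        clusters = np.concatenate([np.arange(n), np.arange(n)])
        try:
            fit = fit_cox_arrays(
                time, event, X,
                clusters=clusters if "unstratified_cox_robust" in estimators else None,
            )
            b = float(fit.beta[0])
            if "unstratified_cox" in estimators:
                out["unstratified_cox"] = (b, float(fit.se_model[0]))
            if "unstratified_cox_robust" in estimators:
                out["unstratified_cox_robust"] = (b, float(fit.se_robust[0]))
        except NumericalError:
            for est in need_cox:
                out[est] = None
    return out, logrank_reject


def run_scenario(
    cfg: ScenarioConfig,
    estimators: Sequence[str] = ALL_ESTIMATORS,
    n_reps: int = 2000,
    master_seed: int = 0,
    true_log_marginal: Optional[float] = None,
    alpha: float = 0.05,
    marginal_n_large: int = 200_000,
) -> list[MetricsRow]:
    """Run one simulation cell and summarize estimator performance.

    ``true_log_marginal`` may be precomputed (recommended when running many
    cells with the same beta); otherwise it is computed here via
    :func:`pairhr.simulator.marginal_hr_parameter` (0 exactly when beta=0).
    Replicates where an estimator fails (no comparable pairs, divergence)
    are excluded for that estimator and counted in ``n_failed``.
    """
    cfg.validate()
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    unknown = set(estimators) - set(ALL_ESTIMATORS)
    if unknown:
        raise ConfigError(f"unknown estimators: {sorted(unknown)}")
    if true_log_marginal is None:
        if cfg.beta == 0.0:
            true_log_marginal = 0.0
        else:
            true_log_marginal = marginal_hr_parameter(
                cfg.beta, cfg.frailty_sd, cfg.lambda0,
                n_large=marginal_n_large,
                seed=replicate_seed(master_seed, n_reps + 1),
            ).log_marginal_hr

    z = stats.norm.ppf(1 - alpha / 2)
    results = {est: [] for est in estimators}
    n_failed = {est: 0 for est in estimators}
    logrank_rejects = []
    for rep in range(n_reps):
        out, lr = _one_replicate(cfg, replicate_seed(master_seed, rep), estimators, alpha, z)
        for est in estimators:
            r = out.get(est)
            if r is None:
                n_failed[est] += 1
            else:
                results[est].append(r)
        if lr is not None:
            logrank_rejects.append(lr)

    targets = {"conditional": cfg.beta, "marginal": true_log_marginal}
    rows: list[MetricsRow] = []
    for est in estimators:
        arr = np.array(results[est], dtype=float)
        lr_rate = (
            float(np.mean(logrank_rejects))
            if est == "stratified_pmle" and logrank_rejects
            else None
        )
        for target_name, truth in targets.items():
            if arr.shape[0] < 2:
                rows.append(MetricsRow(
                    estimator=est, target=target_name, true_value=truth,
                    bias=math.nan, mcse=math.nan, mese=math.nan,
                    rmse=math.nan, coverage=math.nan, rejection_rate=math.nan,
                    n_reps_used=arr.shape[0] if arr.ndim == 2 else 0,
                    n_failed=n_failed[est],
                    logrank_rejection_rate=lr_rate,
                ))
                continue
            metrics = summarize_estimates(arr[:, 0], arr[:, 1], truth, alpha)
            rows.append(MetricsRow(
                estimator=est, target=target_name, true_value=truth,
                n_reps_used=arr.shape[0], n_failed=n_failed[est],
                logrank_rejection_rate=lr_rate, **metrics,
            ))
    return rows


_TABLE_CELLS = {
    "table3": [Censoring("independent", rate=r) for r in (1.0, 2.0, 4.0)],
    "table4": [
        Censoring("conditional", alpha=a)
        for a in (math.log(0.25), 0.0, math.log(4.0))
    ],
}
_BETAS = (math.log(2.0), 0.0, math.log(0.5))


def replicate_table(
    which: str,
    n_pairs: int = 250,
    n_reps: int = 2000,
    master_seed: int = 0,
    estimators: Sequence[str] = ALL_ESTIMATORS,
    marginal_n_large: int = 200_000,
) -> pd.DataFrame:
    """Run the full 3 (beta) x 3 (censoring) scenario grid of one table.

    ``which`` is ``'table3'`` (independent censoring, rates 1/2/4) or
    ``'table4'`` (pair- and exposure-dependent censoring, rate ratios
    0.25/1/4).  Returns a tidy frame, one row per
    (beta, censoring, estimator, target).
    """
    if which not in _TABLE_CELLS:
        raise ConfigError("which must be 'table3' or 'table4'")
    marginal_truths = {}
    for i, beta in enumerate(_BETAS):
        if beta == 0.0:
            marginal_truths[beta] = 0.0
        else:
            marginal_truths[beta] = marginal_hr_parameter(
                beta, n_large=marginal_n_large,
                seed=replicate_seed(master_seed, 10_000 + i),
            ).log_marginal_hr
    records = []
    for bi, beta in enumerate(_BETAS):
        for ci, cens in enumerate(_TABLE_CELLS[which]):
            cfg = ScenarioConfig(n_pairs=n_pairs, beta=beta, censoring=cens)
            t0 = _time.perf_counter()
            rows = run_scenario(
                cfg, estimators, n_reps,
                master_seed=replicate_seed(master_seed, 100 * (bi + 1) + ci),
                true_log_marginal=marginal_truths[beta],
            )
            dt = _time.perf_counter() - t0
            logger.info(
                "cell beta=%.4f censoring=%s: %d reps in %.1fs", beta, cens, n_reps, dt
            )
            for r in rows:
                records.append({
                    "beta": beta, "censoring": str(cens),
                    "estimator": r.estimator, "target": r.target,
                    "true_value": r.true_value, "bias": r.bias,
                    "mcse": r.mcse, "mese": r.mese, "rmse": r.rmse,
                    "coverage": r.coverage, "rejection_rate": r.rejection_rate,
                    "logrank_rejection_rate": r.logrank_rejection_rate,
                    "n_reps_used": r.n_reps_used, "n_failed": r.n_failed,
                })
    return pd.DataFrame(records)
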