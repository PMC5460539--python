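"""Propensity-score estimation and caliper pair-matching without replacement.

The matching recipe mirrors standard cohort-construction practice: fit a
logistic model for exposure on the supplied covariate columns, then greedily
pair each exposed subject to the nearest still-available unexposed subject
whose estimated score lies within a caliper equal to a fraction (default
20%) of the standard deviation of scores in the unexposed (reference)
group.  The greedy order — exposed subjects by descending score, i.e.
hardest to match first — and the subject-id tie-break are documented
choices; they can change which pairs form, rarely how many.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import RankError, SeparationError, ValidationError

__all__ = ["MatchResult", "fit_propensity", "caliper_match", "matched_long_frame"]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of caliper matching: pairs and the leftovers."""

    pairs: list  # (exposed_id, unexposed_id, ps_distance)
    caliper: float
    unmatched_exposed: list
    unmatched_unexposed: list

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def fit_propensity(
    df: pd.DataFrame,
    covariates: Sequence[str],
    exposure_col: str = "exposure",
) -> np.ndarray:
    """Maximum-likelihood logistic propensity scores, one per row.

    The model is exposure ~ intercept + covariates, fitted by IRLS; any
    covariate transformation is the caller's responsibility.  Raises on a
    rank-deficient design (naming the collinear columns) and on complete
    separation.
    """
    missing = [c for c in (exposure_col, *covariates) if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    y = df[exposure_col].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("exposure must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("both exposure groups must be nonempty")
    X = df[list(covariates)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("covariates must be finite")
    design = np.column_stack([np.ones(len(df)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns involved in the deficiency via QR diagonal
        _, R = np.linalg.qr(design)
        diag = np.abs(np.diag(R))
        bad = [
            list(covariates)[j - 1]
            for j in range(1, design.shape[1])
            if diag[j] < 1e-8 * max(diag.max(), 1.0)
        ]
        raise RankError(f"rank-deficient design; collinear columns: {bad or 'intercept'}")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if np.max(np.abs(res.params)) > 30:
        raise SeparationError(
            "logistic coefficients diverging: (quasi-)complete separation"
        )
    scores = np.asarray(res.predict(design), dtype=float)
    return scores


def caliper_match(
    scores: np.ndarray,
    exposure: np.ndarray,
    caliper_sd_fraction: float = 0.2,
    ids: Optional[Sequence] = None,
) -> MatchResult:
    """Greedy nearest-neighbor caliper matching without replacement.

    The caliper is ``caliper_sd_fraction`` times the SD (ddof=1) of the
    scores in the unexposed reference group.  Exposed subjects are processed
    in descending score order (ties by id); each takes the nearest available
    unexposed subject within the caliper (distance ties by id).
    Deterministic for fixed input.
    """
    scores = np.asarray(scores, dtype=float)
    exposure = np.asarray(exposure, dtype=int)
    if scores.shape != exposure.shape:
        raise ValidationError("scores and exposure must have the same length")
    if ids is None:
        ids = np.arange(len(scores))
    ids = np.asarray(ids, dtype=object)
    exp_mask = exposure == 1
    ref_scores = scores[~exp_mask]
    if len(ref_scores) == 0 or len(scores[exp_mask]) == 0:
        raise ValidationError("both exposure groups must be nonempty")
    sd_ref = float(np.std(ref_scores, ddof=1)) if len(ref_scores) > 1 else 0.0
    if sd_ref == 0.0:
        raise ValidationError(
            "zero SD of reference-group scores: degenerate caliper"
        )
    caliper = caliper_sd_fraction * sd_ref

    exp_idx = np.where(exp_mask)[0]
    ctl_idx = np.where(~exp_mask)[0]
    # descending score, then id, for a deterministic hardest-first order
    exp_order = sorted(exp_idx, key=lambda i: (-scores[i], str(ids[i])))
    available = set(ctl_idx.tolist())
    pairs = []
    for i in exp_order:
        best = None
        best_key = None
        for j in available:
            d = abs(scores[i] - scores[j])
            if d <= caliper:
                key = (d, str(ids[j]))
                if best_key is None or key < best_key:
                    best, best_key = j, key
        if best is not None:
            available.discard(best)
            pairs.append((ids[i], ids[best], float(abs(scores[i] - scores[best]))))
    matched_exp = {p[0] for p in pairs}
    matched_ctl = {p[1] for p in pairs}
    return MatchResult(
        pairs=pairs,
        caliper=float(caliper),
        unmatched_exposed=[ids[i] for i in exp_idx if ids[i] not in matched_exp],
        unmatched_unexposed=[ids[j] for j in ctl_idx if ids[j] not in matched_ctl],
    )


def matched_long_frame(
    df: pd.DataFrame,
    result: MatchResult,
    id_col: str = "subject_id",
    exposure_col: str = "exposure",
) -> pd.DataFrame:
    """Long (subject-per-row) frame of the matched cohort with pair ids.

    Carries through every column of ``df`` and adds ``pair_id``; the output
    feeds :mod:`pairhr.pair_data` when time/event columns are present.
    """
    if id_col not in df.columns:
        raise ValidationError(f"missing id column {id_col!r}")
    indexed = df.set_index(id_col, drop=False)
    records = []
    for k, (eid, uid, _) in enumerate(result.pairs):
        for sid in (eid, uid):
            row = indexed.loc[sid].to_dict()
            row["pair_id"] = k
            records.append(row)
    return pd.DataFrame(records)
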