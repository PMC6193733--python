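"""Joint maximum likelihood estimation of the dichotomous Rasch model.

For a 0/1 response matrix the model is ``P(d_ij = 1) = logistic(b_i - d_j)``
with person measures ``b`` and item measures ``d`` in logits.  Persons and
items are estimated jointly by alternating damped Newton-Raphson steps on
the joint log-likelihood

    sum over observed (i, j) of  d_ij (b_i - d_j) - log(1 + exp(b_i - d_j)),

with the origin fixed by the convention that the mean item measure is zero.
Missing entries contribute nothing.  Rows or columns whose observed scores
are extreme (all 0 or all 1) carry no finite MLE and are excluded from
estimation and reported in the excluded index sets.

This is the engine the method of successive dichotomizations calls once per
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import ConvergenceError, DegenerateDataError, DichotomizedMatrix

__all__ = ["DichotomousFit", "jmle_fit"]

logger = logging.getLogger("msdrasch")

# damping: single Newton steps are clipped to this many logits per sweep
_MAX_STEP = 1.0


@dataclass
class DichotomousFit:
    """Result of a dichotomous Rasch JMLE run.

    Excluded (extreme-score) persons/items have NaN measures and appear in
    the ``excluded_*`` index arrays.  ``item_measures`` average to zero over
    included items.
    """

    person_measures: np.ndarray
    item_measures: np.ndarray
    person_se: np.ndarray
    item_se: np.ndarray
    excluded_persons: np.ndarray
    excluded_items: np.ndarray
    n_iterations: int
    max_abs_step: float
    max_score_residual: float
    converged: bool
    level: int | None = None
    log_likelihood: float = field(default=np.nan)


def _find_extreme(obs: np.ndarray, x: np.ndarray):
    """Iteratively flag rows/columns with extreme or empty observed scores."""
    keep_r = np.ones(x.shape[0], dtype=bool)
    keep_c = np.ones(x.shape[1], dtype=bool)
    while True:
        sub_obs = obs & keep_r[:, None] & keep_c[None, :]
        n_r = sub_obs.sum(axis=1)
        s_r = np.where(sub_obs, x, 0.0).sum(axis=1)
        bad_r = keep_r & ((n_r == 0) | (s_r == 0) | (s_r == n_r))
        n_c = sub_obs.sum(axis=0)
        s_c = np.where(sub_obs, x, 0.0).sum(axis=0)
        bad_c = keep_c & ((n_c == 0) | (s_c == 0) | (s_c == n_c))
        if not bad_r.any() and not bad_c.any():
            return keep_r, keep_c
        keep_r &= ~bad_r
        keep_c &= ~bad_c
        if not keep_r.any() or not keep_c.any():
            return keep_r, keep_c


def jmle_fit(
    D: DichotomizedMatrix,
    tolerance: float = 1e-6,
    max_iterations: int = 1000,
) -> DichotomousFit:
    """Fit person and item measures to a dichotomized matrix by JMLE.

    Parameters
    ----------
    D
        0/1 matrix with NaN for missing entries.
    tolerance
        Convergence criterion: the largest absolute Newton step (logits)
        across persons and items in a sweep.
    max_iterations
        Maximum number of alternating sweeps; exceeding it raises
        :class:`ConvergenceError` carrying the last iterate.
    """
    x = D.data
    obs = D.observed
    keep_r, keep_c = _find_extreme(obs, np.nan_to_num(x))
    if keep_r.sum() < 2 or keep_c.sum() < 2:
        raise DegenerateDataError(
            "need at least 2 persons and 2 items with non-extreme scores "
            f"(level h={D.level}); responses carry no joint information"
        )

    sub = np.nan_to_num(x[np.ix_(keep_r, keep_c)])
    m = obs[np.ix_(keep_r, keep_c)]
    sub = np.where(m, sub, 0.0)
    n_pers = m.sum(axis=1)
    n_item = m.sum(axis=0)
    score_pers = sub.sum(axis=1)
    score_item = sub.sum(axis=0)

    # logit-of-proportion starting values, items centred
    b = np.log(score_pers / (n_pers - score_pers))
    d = -np.log(score_item / (n_item - score_item))
    d -= d.mean()

    it = 0
    max_step = np.inf
    for it in range(1, max_iterations + 1):
        p = np.where(m, expit(b[:, None] - d[None, :]), 0.0)
        w = p * (1.0 - p)
        # person block
        resid_p = score_pers - p.sum(axis=1)
        step_b = np.clip(resid_p / w.sum(axis=1), -_MAX_STEP, _MAX_STEP)
        b = b + step_b
        # item block (recompute probabilities at updated persons)
        p = np.where(m, expit(b[:, None] - d[None, :]), 0.0)
        w = p * (1.0 - p)
        resid_i = score_item - p.sum(axis=0)
        step_d = np.clip(-resid_i / w.sum(axis=0), -_MAX_STEP, _MAX_STEP)
        d = d + step_d
        # re-anchor the origin at the mean item measure
        c = d.mean()
        d -= c
        b -= c
        max_step = max(np.abs(step_b).max(), np.abs(step_d).max())
        if max_step < tolerance:
            break
    p = np.where(m, expit(b[:, None] - d[None, :]), 0.0)
    w = p * (1.0 - p)
    resid = np.where(m, sub - p, 0.0)
    max_resid = max(
        np.abs(resid.sum(axis=1)).max(), np.abs(resid.sum(axis=0)).max()
    )
    converged = max_step < tolerance
    logger.debug(
        "jmle level=%s iters=%d max_step=%.3g max_score_resid=%.3g",
        D.level, it, max_step, max_resid,
    )

    bm = np.full(x.shape[0], np.nan)
    dm = np.full(x.shape[1], np.nan)
    bse = np.full(x.shape[0], np.nan)
    dse = np.full(x.shape[1], np.nan)
    bm[keep_r] = b
    dm[keep_c] = d
    bse[keep_r] = 1.0 / np.sqrt(w.sum(axis=1))
    dse[keep_c] = 1.0 / np.sqrt(w.sum(axis=0))
    z = b[:, None] - d[None, :]
    ll = float(np.sum(np.where(m, sub * z - np.logaddexp(0.0, z), 0.0)))
    fit = DichotomousFit(
        person_measures=bm,
        item_measures=dm,
        person_se=bse,
        item_se=dse,
        excluded_persons=np.flatnonzero(~keep_r),
        excluded_items=np.flatnonzero(~keep_c),
        n_iterations=it,
        max_abs_step=float(max_step),
        max_score_residual=float(max_resid),
        converged=converged,
        level=D.level,
        log_likelihood=ll,
    )
    if not converged:
        raise ConvergenceError(
            f"JMLE did not converge in {max_iterations} sweeps "
            f"(last max step {max_step:.3g} logits)",
            last_fit=fit,
        )
    return fit
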