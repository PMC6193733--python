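"""JMLE for the Andrich rating scale model (the comparison baseline).

The model gives ``p(C_h)`` proportional to ``exp(sum_{q<=h}(gamma - tau_q))``
with ``gamma = beta_i - delta_j`` and common thresholds across items.  It
imposes no ordering on the thresholds, and with many sparsely-used
categories its estimated thresholds routinely come out disordered — the
behaviour this package exists to contrast with the ordered-threshold
estimator.

Estimation is joint maximum likelihood by blockwise damped Newton-Raphson:

* person block:     score = observed raw score - expected,  info = rating
  variance summed over that person's observed items;
* item block:       the negatives of the same quantities summed by item;
* threshold block:  for each q, score = sum over observed cells of
  ``P(rating >= q) - [r >= q]``, diagonal information
  ``sum P(>=q)(1 - P(>=q))``.

Identifiability is fixed by mean item measure = 0 and sum of thresholds
= 0 (re-anchored every sweep).  Persons/items whose observed ratings are
all 0 or all L are excluded, as in the dichotomous engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .data import (
    ConvergenceError,
    DegenerateCategoryError,
    DegenerateDataError,
    RatingMatrix,
)
from .model_core import andrich_category_probabilities

__all__ = ["AndrichFit", "andrich_jmle_fit"]

logger = logging.getLogger("msdrasch")

_MAX_STEP = 1.0


@dataclass
class AndrichFit:
    """Andrich rating-scale JMLE result.

    Thresholds are reported exactly as estimated — possibly disordered —
    with ``disorder_flags[h]`` set when ``tau[h] >= tau[h+1]``.
    """

    person_measures: np.ndarray
    item_measures: np.ndarray
    thresholds: np.ndarray
    person_se: np.ndarray
    item_se: np.ndarray
    threshold_se: np.ndarray
    disorder_flags: np.ndarray
    excluded_persons: np.ndarray
    excluded_items: np.ndarray
    n_iterations: int
    max_abs_step: float
    converged: bool

    @property
    def n_thresholds(self) -> int:
        return self.thresholds.size

    @property
    def any_disordered(self) -> bool:
        return bool(self.disorder_flags.any())


def _probs(b, d, tau):
    """Category probabilities for every (person, item) cell: (N, M, L+1).

    Single-pass softmax of the cumulative exponents; equivalent to
    :func:`msdrasch.model_core.andrich_category_probabilities` but cheaper
    inside the estimation loop.
    """
    gamma = b[:, None] - d[None, :]
    h = np.arange(1, tau.size + 1, dtype=float)
    log_num = np.concatenate(
        [
            np.zeros(gamma.shape + (1,)),
            h * gamma[..., None] - np.cumsum(tau),
        ],
        axis=-1,
    )
    return softmax(log_num, axis=-1)


def _find_extreme(r: np.ndarray, obs: np.ndarray, L: int):
    keep_r = np.ones(r.shape[0], dtype=bool)
    keep_c = np.ones(r.shape[1], dtype=bool)
    while True:
        sub = obs & keep_r[:, None] & keep_c[None, :]
        n_r = sub.sum(axis=1)
        s_r = np.where(sub, r, 0.0).sum(axis=1)
        bad_r = keep_r & ((n_r == 0) | (s_r == 0) | (s_r == L * n_r))
        n_c = sub.sum(axis=0)
        s_c = np.where(sub, r, 0.0).sum(axis=0)
        bad_c = keep_c & ((n_c == 0) | (s_c == 0) | (s_c == L * n_c))
        if not bad_r.any() and not bad_c.any():
            return keep_r, keep_c
        keep_r &= ~bad_r
        keep_c &= ~bad_c
        if not keep_r.any() or not keep_c.any():
            return keep_r, keep_c


def andrich_jmle_fit(
    R: RatingMatrix,
    tolerance: float = 1e-6,
    max_iterations: int = 2000,
) -> AndrichFit:
    """Fit the Andrich rating scale model by joint maximum likelihood.

    Raises :class:`DegenerateCategoryError` if any category 0..L is never
    observed (its threshold would be inestimable) and
    :class:`ConvergenceError` (carrying the last iterate) if the sweep
    limit is reached.
    """
    L = R.n_thresholds
    counts = R.category_counts()
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0)
        raise DegenerateCategoryError(
            f"categories {missing.tolist()} are never observed; Andrich "
            "thresholds for unused categories are inestimable"
        )
    x = R.ratings
    obs = R.observed
    keep_r, keep_c = _find_extreme(np.nan_to_num(x), obs, L)
    if keep_r.sum() < 2 or keep_c.sum() < 2:
        raise DegenerateDataError(
            "need at least 2 persons and 2 items with non-extreme totals"
        )
    sub = np.where(obs, np.nan_to_num(x), 0.0)[np.ix_(keep_r, keep_c)]
    m = obs[np.ix_(keep_r, keep_c)]
    n_pers = m.sum(axis=1)
    n_item = m.sum(axis=0)
    score_pers = sub.sum(axis=1)
    score_item = sub.sum(axis=0)

    # crude logit starts from relative raw scores
    prop_p = score_pers / (L * n_pers)
    prop_i = score_item / (L * n_item)
    b = np.log(prop_p / (1 - prop_p))
    d = -np.log(prop_i / (1 - prop_i))
    d -= d.mean()
    # thresholds start at minus the logit of the cumulative proportions,
    # which is exact for a single person-item pair and a decent anchor here
    n_obs = m.sum()
    cum_prop = np.array(
        [np.where(m, sub >= q, False).sum() / n_obs for q in range(1, L + 1)]
    )
    tau = -np.log(cum_prop / (1 - cum_prop))
    tau -= tau.mean()
    hgrid = np.arange(L + 1, dtype=float)

    # precomputed indicators 1[r >= q] for the threshold score
    dq = sub[..., None] >= np.arange(1, L + 1)
    dq_tot = np.where(m[..., None], dq, 0.0).sum(axis=(0, 1))
    pair_max = np.maximum.outer(np.arange(L), np.arange(L))

    h2grid = hgrid**2

    def _moments(p):
        e = p @ hgrid
        v = p @ h2grid - e**2
        return e, v

    it = 0
    max_step = np.inf
    for it in range(1, max_iterations + 1):
        # Gauss-Seidel: each block takes a damped Newton step from a fresh
        # probability evaluation (simultaneous block updates oscillate)
        p = _probs(b, d, tau)
        e, v = _moments(p)
        resid = np.where(m, sub - e, 0.0)
        info = np.where(m, v, 0.0)
        step_b = np.clip(
            resid.sum(axis=1) / info.sum(axis=1), -_MAX_STEP, _MAX_STEP
        )
        b = b + step_b

        p = _probs(b, d, tau)
        e, v = _moments(p)
        resid = np.where(m, sub - e, 0.0)
        info = np.where(m, v, 0.0)
        step_d = np.clip(
            -resid.sum(axis=0) / info.sum(axis=0), -_MAX_STEP, _MAX_STEP
        )
        d = d + step_d
        c = d.mean()
        d -= c
        b -= c

        if L > 1:
            p = _probs(b, d, tau)
            cum_ge = np.cumsum(p[..., ::-1], axis=-1)[..., ::-1]  # P(X >= h)
            pge = cum_ge[..., 1:]
            pq = np.where(m[..., None], pge, 0.0)
            s_tot = pq.sum(axis=(0, 1))
            sc = s_tot - dq_tot
            # full observed information of the threshold block:
            # sum over cells of Cov(1[X>=q], 1[X>=r]) = P(X>=max(q,r)) -
            # P(X>=q) P(X>=r); the diagonal alone leaves slowly decaying
            # coupled modes at large L
            info_t = s_tot[pair_max] - np.einsum("nmq,nmr->qr", pq, pge)
            info_t = info_t + np.eye(L) * (1e-9 * np.trace(info_t))
            step_t = np.linalg.solve(info_t, sc)
            nrm = np.abs(step_t).max()
            if nrm > _MAX_STEP:
                step_t *= _MAX_STEP / nrm
            tau = tau + step_t
            t = tau.mean()
            tau -= t
            b -= t
        else:
            step_t = np.zeros(1)
        max_step = max(
            np.abs(step_b).max(), np.abs(step_d).max(), np.abs(step_t).max()
        )
        if max_step < tolerance:
            break

    p = _probs(b, d, tau)
    e = np.sum(hgrid * p, axis=-1)
    v = np.where(m, np.sum((hgrid - e[..., None]) ** 2 * p, axis=-1), 0.0)
    cum_ge = np.cumsum(p[..., ::-1], axis=-1)[..., ::-1]
    pq = cum_ge[..., 1:]
    iq = np.where(m[..., None], pq * (1 - pq), 0.0).sum(axis=(0, 1))
    converged = max_step < tolerance
    logger.debug(
        "andrich jmle L=%d iters=%d max_step=%.3g", L, it, max_step
    )

    bm = np.full(x.shape[0], np.nan)
    dm = np.full(x.shape[1], np.nan)
    bse = np.full(x.shape[0], np.nan)
    dse = np.full(x.shape[1], np.nan)
    bm[keep_r] = b
    dm[keep_c] = d
    bse[keep_r] = 1.0 / np.sqrt(v.sum(axis=1))
    dse[keep_c] = 1.0 / np.sqrt(v.sum(axis=0))
    fitres = AndrichFit(
        person_measures=bm,
        item_measures=dm,
        thresholds=tau,
        person_se=bse,
        item_se=dse,
        threshold_se=1.0 / np.sqrt(iq),
        disorder_flags=np.diff(tau) <= 0,
        excluded_persons=np.flatnonzero(~keep_r),
        excluded_items=np.flatnonzero(~keep_c),
        n_iterations=it,
        max_abs_step=float(max_step),
        converged=converged,
    )
    if not converged:
        raise ConvergenceError(
            f"Andrich JMLE did not converge in {max_iterations} sweeps "
            f"(last max step {max_step:.3g} logits)",
            last_fit=fitres,
        )
    return fitres
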