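"""Category-probability functions for the two rating scale models.

Both models place persons (beta), items (delta) and category thresholds
(tau) on a common logit scale and work with the difference
``gamma = beta - delta``.

*Ordered-threshold (MSD) model*: a rating scale is a real line partitioned
by strictly ordered thresholds into ordered categories, so the probability
of a rating at or above category ``h`` is a single logistic function of
``gamma - tau_h``, and category probabilities are differences of adjacent
cumulative curves.  This is a graded-response form with unit discrimination
and thresholds shared across items; disordered thresholds would yield
negative probabilities and are rejected.

*Andrich rating scale model*: the classical polytomous Rasch form in which
``p(C_h)`` is proportional to ``exp(sum_{q<=h} (gamma - tau_q))``.  It
imposes no ordering on the thresholds.

At ``L = 1`` both reduce to the dichotomous Rasch model
``p = exp(gamma - tau) / (1 + exp(gamma - tau))``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .data import ThresholdOrderError

__all__ = [
    "cumulative_probability",
    "msd_category_probabilities",
    "expected_rating_and_variance",
    "andrich_category_probabilities",
    "andrich_expected_and_variance",
    "log_likelihood_msd",
]


def _check_finite(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def _check_ordered(tau: np.ndarray) -> np.ndarray:
    tau = _check_finite("tau", np.atleast_1d(tau))
    if tau.ndim != 1 or tau.size < 1:
        raise ValueError("tau must be a 1-D array of at least one threshold")
    if np.any(np.diff(tau) <= 0):
        raise ThresholdOrderError(
            "thresholds must be strictly increasing; disordered thresholds "
            "produce negative category probabilities"
        )
    return tau


def cumulative_probability(gamma, tau_h):
    """P(rating >= h) = logistic(gamma - tau_h).

    Strictly increasing in ``gamma`` and strictly decreasing in ``tau_h``.
    Accepts scalars or broadcastable arrays.
    """
    gamma = _check_finite("gamma", gamma)
    tau_h = _check_finite("tau_h", tau_h)
    return expit(gamma - tau_h)


def msd_category_probabilities(gamma, tau):
    """Category probabilities p(C_0)..p(C_L) of the ordered-threshold model.

    ``p(C_h) = F(gamma - tau_h) - F(gamma - tau_{h+1})`` with
    ``F = logistic``, ``F(gamma - tau_0) := 1`` and
    ``F(gamma - tau_{L+1}) := 0``.  ``tau`` must be strictly increasing.

    Returns an array of shape ``gamma.shape + (L + 1,)``.
    """
    gamma = _check_finite("gamma", gamma)
    tau = _check_ordered(tau)
    g = np.asarray(gamma, dtype=float)[..., None]
    upper = expit(g - tau)  # P(rating >= h), h = 1..L; decreasing in h
    ones = np.ones(g.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    cum = np.concatenate([ones, upper, zeros], axis=-1)
    return cum[..., :-1] - cum[..., 1:]


def expected_rating_and_variance(gamma, tau):
    """Mean and variance of the rating under the ordered-threshold model.

    ``E = sum_h h p(C_h)`` and ``Var = sum_h (h - E)^2 p(C_h)``; used by the
    infit statistic, which compares observed squared residuals to these
    model variances.
    """
    p = msd_category_probabilities(gamma, tau)
    h = np.arange(p.shape[-1], dtype=float)
    e = np.sum(h * p, axis=-1)
    v = np.sum((h - e[..., None]) ** 2 * p, axis=-1)
    return e, v


def andrich_category_probabilities(gamma, tau):
    """Category probabilities of the Andrich rating scale model.

    ``p(C_h)`` proportional to ``exp(sum_{q=1..h} (gamma - tau_q))`` with the
    empty sum for ``h = 0`` equal to 0.  Thresholds may be in any order.
    Computed in log space for stability at large ``|gamma - tau|``.
    """
    gamma = _check_finite("gamma", gamma)
    tau = _check_finite("tau", np.atleast_1d(tau))
    if tau.ndim != 1 or tau.size < 1:
        raise ValueError("tau must be a 1-D array of at least one threshold")
    g = np.asarray(gamma, dtype=float)[..., None]
    h = np.arange(1, tau.size + 1, dtype=float)
    # log numerator for category h: h*gamma - cumsum(tau)_h, zero for h=0
    log_num = np.concatenate(
        [np.zeros(g.shape[:-1] + (1,)), h * g - np.cumsum(tau)], axis=-1
    )
    logp = log_num - logsumexp(log_num, axis=-1, keepdims=True)
    return np.exp(logp)


def andrich_expected_and_variance(gamma, tau):
    """Rating mean and variance under the Andrich model."""
    p = andrich_category_probabilities(gamma, tau)
    h = np.arange(p.shape[-1], dtype=float)
    e = np.sum(h * p, axis=-1)
    v = np.sum((h - e[..., None]) ** 2 * p, axis=-1)
    return e, v


def log_likelihood_msd(gamma, tau, ratings):
    """Pointwise log-likelihood of integer ratings under the ordered model.

    ``gamma`` and ``ratings`` must have the same shape.  The boundary
    categories use ``log_expit`` directly, which stays finite for extreme
    logits where a log of a probability difference would underflow.
    """
    g = np.asarray(gamma, dtype=float)
    r = np.asarray(ratings, dtype=int)
    flat_g = np.atleast_1d(g).ravel()
    flat_r = np.atleast_1d(r).ravel()
    p = msd_category_probabilities(flat_g, tau)
    with np.errstate(divide="ignore"):
        out = np.log(p[np.arange(flat_r.size), flat_r])
    out = np.where(flat_r == 0, log_expit(-(flat_g - tau[0])), out)
    out = np.where(flat_r == len(tau), log_expit(flat_g - tau[-1]), out)
    if g.ndim == 0:
        return float(out[0])
    return out.reshape(g.shape)
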