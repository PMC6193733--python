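"""Shared fixtures and independent estimation oracles for the test suite.

The oracles deliberately avoid the package's Newton/root-finding paths:
they maximize the same likelihoods by coordinate ascent over a fixed
lattice, so agreement between the two routes checks the estimators against
an implementation-independent target.
"""

from __future__ import annotations

import numpy as np
import pytest

from msdrasch import RatingMatrix, SimulationConfig, simulate
from msdrasch.model_core import andrich_category_probabilities


# ---------------------------------------------------------------------------
# lattice coordinate-ascent oracles
# ---------------------------------------------------------------------------


def dichotomous_loglik(x, obs, b, d):
    z = b[:, None] - d[None, :]
    return float(np.sum(np.where(obs, x * z - np.logaddexp(0.0, z), 0.0)))


def grid_mle_dichotomous(x, obs, step=0.001, span=6.0, sweeps=60):
    """Lattice coordinate-ascent MLE of the dichotomous Rasch likelihood.

    Persons and items move one at a time to the best value on a fixed
    lattice; items are re-centred to mean zero at the end (the likelihood
    is flat along the common-shift direction).
    """
    n, mcols = x.shape
    grid = np.arange(-span, span + step / 2, step)
    b = np.zeros(n)
    d = np.zeros(mcols)
    for _ in range(sweeps):
        moved = 0.0
        for i in range(n):
            z = grid[:, None] - d[None, :]
            ll = np.where(obs[i], x[i] * z - np.logaddexp(0.0, z), 0.0).sum(axis=1)
            new = grid[np.argmax(ll)]
            moved = max(moved, abs(new - b[i]))
            b[i] = new
        for j in range(mcols):
            z = b[:, None] - grid[None, :]
            ll = np.where(
                obs[:, j][:, None], x[:, j][:, None] * z - np.logaddexp(0.0, z), 0.0
            ).sum(axis=0)
            new = grid[np.argmax(ll)]
            moved = max(moved, abs(new - d[j]))
            d[j] = new
        if moved < step / 2:
            break
    c = d.mean()
    return b - c, d - c


def andrich_loglik(r, obs, b, d, tau):
    gamma = b[:, None] - d[None, :]
    p = andrich_category_probabilities(gamma, tau)
    idx = np.where(obs, r.astype(int), 0)
    pr = np.take_along_axis(p, idx[..., None], axis=-1)[..., 0]
    return float(np.sum(np.where(obs, np.log(pr), 0.0)))


def _andrich_ll_rows(gamma, tau, r, obs):
    """Log-likelihood summed over the trailing axes for stacked gammas."""
    p = andrich_category_probabilities(gamma, tau)
    idx = np.broadcast_to(np.where(obs, r.astype(int), 0), gamma.shape)
    pr = np.take_along_axis(p, idx[..., None], axis=-1)[..., 0]
    axes = tuple(range(1, gamma.ndim))
    return np.where(obs, np.log(pr), 0.0).sum(axis=axes)


def grid_mle_andrich(r, obs, L, step=0.001, span=6.0, sweeps=60):
    """Lattice coordinate-ascent MLE of the Andrich rating-scale likelihood.

    Each coordinate scans the full lattice (vectorized); returns
    (b, d, tau) anchored at mean item 0 and sum of thresholds 0.
    """
    n, mcols = r.shape
    grid = np.arange(-span, span + step / 2, step)
    b = np.zeros(n)
    d = np.zeros(mcols)
    tau = np.zeros(L)
    for _ in range(sweeps):
        moved = 0.0
        for i in range(n):
            gam = grid[:, None] - d[None, :]
            ll = _andrich_ll_rows(gam, tau, r[i], obs[i])
            new = grid[np.argmax(ll)]
            moved = max(moved, abs(new - b[i]))
            b[i] = new
        for j in range(mcols):
            gam = b[None, :] - grid[:, None]
            ll = _andrich_ll_rows(gam, tau, r[:, j], obs[:, j])
            new = grid[np.argmax(ll)]
            moved = max(moved, abs(new - d[j]))
            d[j] = new
        for q in range(L):
            # coarse-to-fine scan keeps each likelihood tensor small
            cand = tau.copy()
            coarse = np.arange(-span, span + 0.05, 0.05)
            lls = []
            for v in coarse:
                cand[q] = v
                lls.append(andrich_loglik(r, obs, b, d, cand))
            v0 = coarse[int(np.argmax(lls))]
            fine = np.arange(v0 - 0.06, v0 + 0.06 + step / 2, step)
            lls = []
            for v in fine:
                cand[q] = v
                lls.append(andrich_loglik(r, obs, b, d, cand))
            new = fine[int(np.argmax(lls))]
            moved = max(moved, abs(new - tau[q]))
            tau[q] = new
        if moved < step / 2:
            break
    c = d.mean()
    d = d - c
    b = b - c
    t = tau.mean()
    tau = tau - t
    b = b - t
    return b, d, tau


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_sim():
    """200 x 20, L = 4 simulated study with the reference noise levels."""
    cfg = SimulationConfig(
        n_persons=200, n_items=20, n_thresholds=4, seed=20260930
    )
    R, truth, rec = simulate(cfg)
    return R, truth, rec


@pytest.fixture()
def tiny_matrix():
    """3 x 3 dichotomous matrix with one all-zero (extreme) person."""
    return np.array(
        [[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
    )


@pytest.fixture()
def rating_matrix_small():
    """Hand-written 6 x 4 polytomous matrix with a missing cell."""
    r = np.array(
        [
            [0, 1, 2, 1],
            [2, 2, 1, 2],
            [1, 0, 0, 1],
            [2, 1, 2, 2],
            [0, 0, 1, 0],
            [1, 2, np.nan, 1],
        ],
        dtype=float,
    )
    return RatingMatrix(ratings=r, max_category=2)
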