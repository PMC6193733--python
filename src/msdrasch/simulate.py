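"""Simulation of rating-scale responses with ordered per-trial thresholds.

The generative process emulated here:

* True person measures, item measures and thresholds are drawn uniformly on
  a configurable interval (default [-2, 2]); item measures are centred to
  mean zero and thresholds are sorted after drawing.
* Each of the K = N x M person-item encounters ("trials") uses its own set
  of L strictly ordered thresholds.  Sets are built by a
  correlate-then-decorrelate algorithm (below) so that every set is ordered
  while each threshold's deviates keep the desired marginal distribution
  (standard normal by default).
* On each trial the quantity ``v = beta_i - delta_j + eps`` with
  ``eps ~ Normal(0, trial_error_sd)`` is compared to that trial's
  thresholds; the rating is the category whose half-open interval
  ``[tau_h, tau_{h+1})`` contains v (closed on the left, so v exactly at a
  threshold takes the higher category).
* Entries are finally deleted missing-at-random with the configured
  probability.

Decorrelation: first draw one deviate per set and add it to all L threshold
means, giving K ordered but perfectly correlated sets; then repeatedly pick
two sets and a threshold index at random and swap that threshold between
the sets when (and only when) both sets stay ordered.  Swapping permutes
values within a threshold, so marginal distributions are preserved exactly
while cross-set correlation decays.  K*L swap attempts are the default.

Rejection sampling (redraw until ordered) would *not* preserve the
marginals — it skews them — which is why the swap algorithm is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import msd as msd_mod
from .andrich import AndrichFit, andrich_jmle_fit
from .data import DegenerateDataError, RatingMatrix, ThresholdOrderError
from .msd import MSDFit, merge_categories

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "draw_true_parameters",
    "generate_threshold_sets",
    "simulate_ratings",
    "simulate",
    "ConditionResult",
    "ReplicationResult",
    "ReplicationSummary",
    "run_replication_study",
    "summarize_replication",
]

logger = logging.getLogger("msdrasch")


@dataclass
class SimulationConfig:
    """Design of one simulated rating-scale study.

    Defaults are the reference study conditions: 1000 persons, 100 items,
    9 thresholds (10 categories), true parameters uniform on [-2, 2], unit
    standard-normal error on person-minus-item differences, unit
    standard-normal within-person threshold deviates, and 10% of entries
    missing at random.
    """

    n_persons: int = 1000
    n_items: int = 100
    n_thresholds: int = 9
    parameter_range: tuple[float, float] = (-2.0, 2.0)
    trial_error_sd: float = 1.0
    threshold_error_sd: float = 1.0
    missing_probability: float = 0.10
    decorrelation_iterations: int | None = None  # default K * L
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_persons, self.n_items, self.n_thresholds) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.parameter_range
        if hi < lo:
            raise ValueError("parameter_range must be (low, high)")
        if not 0 <= self.missing_probability < 1:
            raise ValueError("missing_probability must lie in [0, 1)")
        if self.trial_error_sd < 0 or self.threshold_error_sd < 0:
            raise ValueError("error SDs must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["parameter_range"] = list(self.parameter_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "parameter_range" in d:
            d["parameter_range"] = tuple(d["parameter_range"])
        return cls(**d)


@dataclass
class TrueParameters:
    """Ground truth of a simulation: expected values and trial realizations.

    ``threshold_sets`` has shape (K, L): the ordered thresholds used on
    trial k (trials enumerate person-item pairs row-major, k = i*M + j).
    """

    person_measures: np.ndarray
    item_measures: np.ndarray
    thresholds: np.ndarray
    threshold_sets: np.ndarray | None = None


@dataclass
class TrialRecord:
    """Per-trial realizations: the latent comparison and its noise."""

    person_index: np.ndarray
    item_index: np.ndarray
    gamma_true: np.ndarray
    trial_error: np.ndarray
    value: np.ndarray
    rating: np.ndarray
    missing: np.ndarray


def draw_true_parameters(
    config: SimulationConfig, rng: np.random.Generator
) -> TrueParameters:
    """Draw expected person/item measures and sorted thresholds.

    Uniform on ``config.parameter_range``; item measures centred to mean
    zero; thresholds sorted ascending after drawing (ties, possible only
    for a degenerate range, are an error).
    """
    lo, hi = config.parameter_range
    beta = rng.uniform(lo, hi, config.n_persons)
    delta = rng.uniform(lo, hi, config.n_items)
    delta -= delta.mean()
    tau = np.sort(rng.uniform(lo, hi, config.n_thresholds))
    if config.n_thresholds > 1 and np.any(np.diff(tau) == 0):
        raise DegenerateDataError(
            "tied true thresholds (degenerate parameter range?)"
        )
    return TrueParameters(
        person_measures=beta, item_measures=delta, thresholds=tau
    )


def generate_threshold_sets(
    tau_means: np.ndarray,
    deviate_sd: float,
    K: int,
    rng: np.random.Generator,
    iterations: int | None = None,
    return_initial: bool = False,
) -> np.ndarray:
    """K ordered threshold sets by the correlate-then-decorrelate algorithm.

    Start from ``tau_means + deviate_k`` (one deviate per set, so every set
    is ordered and all sets are perfectly correlated), then attempt
    ``iterations`` random order-preserving swaps of a single threshold
    between two random sets (default K*L attempts).  Each threshold's
    marginal across sets is an exact permutation of its initial values.
    """
    tau_means = np.asarray(tau_means, dtype=float)
    if tau_means.ndim != 1 or tau_means.size < 1:
        raise ValueError("tau_means must be a 1-D array")
    if np.any(np.diff(tau_means) <= 0):
        raise ThresholdOrderError("tau_means must be strictly increasing")
    if K < 1:
        raise ValueError("K must be positive")
    L = tau_means.size
    deviates = rng.normal(0.0, deviate_sd, K)
    sets = tau_means[None, :] + deviates[:, None]
    initial = sets.copy()
    n_iter = K * L if iterations is None else int(iterations)
    if deviate_sd > 0 and L > 1 and K > 1:
        si = rng.integers(0, K, n_iter)
        sj = rng.integers(0, K, n_iter)
        hs = rng.integers(0, L, n_iter)
        S = sets  # local alias for the hot loop
        for t in range(n_iter):
            i = si[t]
            j = sj[t]
            if i == j:
                continue
            h = hs[t]
            a = S[i, h]
            c = S[j, h]
            if h > 0 and (S[i, h - 1] >= c or S[j, h - 1] >= a):
                continue
            if h < L - 1 and (c >= S[i, h + 1] or a >= S[j, h + 1]):
                continue
            S[i, h] = c
            S[j, h] = a
    if return_initial:
        return sets, initial
    return sets


def simulate_ratings(
    truth: TrueParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[RatingMatrix, TrialRecord]:
    """Generate the rating matrix from ground truth.

    Ratings follow the half-open category convention: trial value exactly
    at a threshold takes the category whose lower bound it is.
    """
    N, M, L = config.n_persons, config.n_items, config.n_thresholds
    if truth.threshold_sets is None:
        sets = np.tile(truth.thresholds, (N * M, 1))
    else:
        sets = truth.threshold_sets
    if sets.shape != (N * M, L):
        raise ValueError("threshold_sets must have shape (N*M, L)")
    pid, iid = np.divmod(np.arange(N * M), M)
    gamma = truth.person_measures[pid] - truth.item_measures[iid]
    eps = rng.normal(0.0, config.trial_error_sd, N * M)
    v = gamma + eps
    rating = (v[:, None] >= sets).sum(axis=1)
    miss = rng.random(N * M) < config.missing_probability
    r = rating.astype(float)
    r[miss] = np.nan
    R = RatingMatrix(ratings=r.reshape(N, M), max_category=L)
    rec = TrialRecord(
        person_index=pid,
        item_index=iid,
        gamma_true=gamma,
        trial_error=eps,
        value=v,
        rating=rating,
        missing=miss,
    )
    return R, rec


def simulate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[RatingMatrix, TrueParameters, TrialRecord]:
    """End-to-end draw: truth, per-trial threshold sets, ratings."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = draw_true_parameters(config, rng)
    truth.threshold_sets = generate_threshold_sets(
        truth.thresholds,
        config.threshold_error_sd,
        config.n_persons * config.n_items,
        rng,
        iterations=config.decorrelation_iterations,
    )
    R, rec = simulate_ratings(truth, config, rng)
    return R, truth, rec


# ---------------------------------------------------------------------------
# Replication study: successive rescoring, both estimators per condition
# ---------------------------------------------------------------------------


@dataclass
class ConditionResult:
    """Both model fits at one number of thresholds, with matched truth."""

    n_thresholds: int
    true_thresholds: np.ndarray
    msd_fit: MSDFit
    andrich_fit: AndrichFit
    ratings: RatingMatrix | None = None
    merged_threshold: int | None = None  # q removed to reach the NEXT condition


@dataclass
class ReplicationResult:
    truth: TrueParameters
    conditions: list[ConditionResult] = field(default_factory=list)


@dataclass
class ReplicationSummary:
    """Cross-condition recovery statistics of a replication study.

    Per-condition rows live in ``by_condition`` (one row per threshold
    count and model, with r^2 and OLS slope for each parameter kind).
    Pooled statistics concatenate estimates from every polytomous
    condition (at least 2 thresholds) into one vector against the repeated
    true values; because each estimator carries a per-condition origin and
    scale, pooled r^2 drops exactly when the scale moves across conditions.
    """

    by_condition: pd.DataFrame
    msd_person_r2_pooled: float
    msd_item_r2_pooled: float
    andrich_person_r2_pooled: float
    andrich_item_r2_pooled: float
    msd_mean_item_slope: float

    def condition_stat(self, model: str, kind: str, stat: str) -> pd.Series:
        df = self.by_condition
        sel = df[(df["model"] == model) & (df["kind"] == kind)]
        return sel.set_index("n_thresholds")[stat]


def _pooled_r2(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    from .diagnostics import recovery_summary

    est = np.concatenate([p[0] for p in pairs])
    tru = np.concatenate([p[1] for p in pairs])
    return recovery_summary(est, tru, "pooled").r_squared


def summarize_replication(result: ReplicationResult) -> ReplicationSummary:
    """Recovery r^2 and slopes per condition plus pooled cross-condition r^2."""
    from .diagnostics import recovery_summary

    truth = result.truth
    rows = []
    pooled: dict[tuple[str, str], list] = {
        (m, k): [] for m in ("msd", "andrich") for k in ("person", "item")
    }
    for cond in result.conditions:
        for model, fit in (
            ("msd", cond.msd_fit), ("andrich", cond.andrich_fit)
        ):
            for kind, est, tru in (
                ("person", fit.person_measures, truth.person_measures),
                ("item", fit.item_measures, truth.item_measures),
                ("threshold", fit.thresholds, cond.true_thresholds),
            ):
                if len(est) < 2:
                    continue
                s = recovery_summary(est, tru, kind)
                rows.append(
                    {
                        "n_thresholds": cond.n_thresholds,
                        "model": model,
                        "kind": kind,
                        "r": s.pearson_r,
                        "r2": s.r_squared,
                        "slope": s.best_fit_slope,
                        "intercept": s.best_fit_intercept,
                        "n": s.n,
                    }
                )
                if kind in ("person", "item") and cond.n_thresholds >= 2:
                    pooled[(model, kind)].append((est, tru))
    df = pd.DataFrame(rows)
    msd_slopes = df[
        (df["model"] == "msd") & (df["kind"] == "item")
    ]["slope"]
    return ReplicationSummary(
        by_condition=df,
        msd_person_r2_pooled=_pooled_r2(pooled[("msd", "person")]),
        msd_item_r2_pooled=_pooled_r2(pooled[("msd", "item")]),
        andrich_person_r2_pooled=_pooled_r2(pooled[("andrich", "person")]),
        andrich_item_r2_pooled=_pooled_r2(pooled[("andrich", "item")]),
        msd_mean_item_slope=float(msd_slopes.mean()),
    )


def _choose_merge(andrich_fit: AndrichFit, rule: str) -> int:
    """Pick the threshold index q (1-based) to remove for the next condition.

    ``most_disordered``: the adjacent pair with the largest reversal
    ``tau_h - tau_{h+1}`` (equivalently, the smallest gap when none is
    reversed); the upper threshold of the pair is removed.  ``first``:
    always remove threshold 2 (merge the two lowest categories above 0).
    """
    tau = andrich_fit.thresholds
    if rule == "most_disordered":
        h = int(np.argmax(tau[:-1] - tau[1:]))  # 0-based pair index
        return h + 2  # remove the upper threshold of the pair (1-based)
    if rule == "first":
        return 2
    raise ValueError(f"unknown merge rule {rule!r}")


def run_replication_study(
    config: SimulationConfig,
    merge_rule: str = "most_disordered",
    min_thresholds: int = 1,
    tolerance: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> ReplicationResult:
    """Simulate once, then fit both models while successively rescoring.

    One dataset is simulated at the configured L.  At each condition both
    the successive-dichotomization estimator and the Andrich baseline are
    fit; then one pair of adjacent categories is merged (per ``merge_rule``
    applied to the Andrich thresholds, mirroring the practice of rescoring
    until Andrich thresholds come out ordered) and both models are refit,
    down to ``min_thresholds``.  True thresholds are carried through each
    merge by deleting the removed threshold.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R, truth, _ = simulate(config, rng)
    result = ReplicationResult(truth=truth)
    tau_true = truth.thresholds.copy()
    current = R
    for L_cur in range(config.n_thresholds, min_thresholds - 1, -1):
        msd_fit = msd_mod.fit(current, tolerance=tolerance)
        and_fit = andrich_jmle_fit(current, tolerance=tolerance)
        cond = ConditionResult(
            n_thresholds=L_cur,
            true_thresholds=tau_true.copy(),
            msd_fit=msd_fit,
            andrich_fit=and_fit,
            ratings=current,
        )
        logger.info(
            "condition L=%d: andrich disordered pairs=%d",
            L_cur, int(and_fit.disorder_flags.sum()),
        )
        result.conditions.append(cond)
        if L_cur > min_thresholds:
            q = _choose_merge(and_fit, merge_rule)
            cond.merged_threshold = q
            current = merge_categories(current, q)
            tau_true = np.delete(tau_true, q - 1)
    return result
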