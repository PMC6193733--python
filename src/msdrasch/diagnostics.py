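"""Fit statistics and parameter-recovery analysis.

Covers the quantities used to compare the two estimators on simulated
data: person/item infit mean squares against their chi-squared reference,
binned observed-versus-model probability curves, estimated-versus-true
correlations and slopes, and the analytic slope implied by the error
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .andrich import AndrichFit
from .data import RatingMatrix, UndefinedCorrelationError
from .model_core import (
    andrich_expected_and_variance,
    expected_rating_and_variance,
)
from .msd import MSDFit

__all__ = [
    "RecoverySummary",
    "InfitReport",
    "recovery_summary",
    "infit_mean_squares",
    "probability_curve_data",
    "curve_discrepancy",
    "predicted_slope",
]


@dataclass
class RecoverySummary:
    """Agreement between an estimated and a true parameter vector."""

    parameter_kind: str
    n: int
    pearson_r: float
    r_squared: float
    best_fit_slope: float
    best_fit_intercept: float


def recovery_summary(
    estimates: np.ndarray,
    truth: np.ndarray,
    parameter_kind: str = "parameter",
) -> RecoverySummary:
    """Pearson r, r^2 and OLS slope/intercept of estimates on truth.

    NaN estimates (e.g. fully extreme persons) are dropped pairwise.  The
    regression direction is estimates ~ truth, so the slope measures the
    stretch of the estimated scale relative to the true one.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truth must have equal length")
    ok = np.isfinite(est) & np.isfinite(tru)
    est, tru = est[ok], tru[ok]
    if est.size < 2:
        raise ValueError("need at least 2 finite pairs")
    if np.ptp(tru) == 0:
        raise UndefinedCorrelationError("true values have zero variance")
    res = stats.linregress(tru, est)
    return RecoverySummary(
        parameter_kind=parameter_kind,
        n=int(est.size),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        best_fit_slope=float(res.slope),
        best_fit_intercept=float(res.intercept),
    )


@dataclass
class InfitReport:
    """Infit mean squares with their chi-squared/df reference distribution.

    ``person_infit[i] = sum_j (r_ij - E_ij)^2 / sum_j Var_ij`` over person
    i's observed items; an infit near 1 indicates residual noise at the
    level the model predicts.  The reference CDF is the mixture over
    persons of chi2_df / df at each person's own observed-response count.
    """

    person_infit: np.ndarray
    item_infit: np.ndarray
    person_df: np.ndarray
    item_df: np.ndarray
    grid: np.ndarray
    empirical_cdf: np.ndarray
    reference_cdf: np.ndarray
    max_cdf_discrepancy: float

    @property
    def mean_person_infit(self) -> float:
        return float(np.nanmean(self.person_infit))


def _cell_moments(fit) -> tuple[np.ndarray, np.ndarray]:
    gamma = fit.person_measures[:, None] - fit.item_measures[None, :]
    g = np.where(np.isfinite(gamma), gamma, 0.0)
    if isinstance(fit, MSDFit):
        e, v = expected_rating_and_variance(g, fit.thresholds)
    elif isinstance(fit, AndrichFit):
        e, v = andrich_expected_and_variance(g, fit.thresholds)
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    bad = ~np.isfinite(gamma)
    e = np.where(bad, np.nan, e)
    v = np.where(bad, np.nan, v)
    return e, v


def infit_mean_squares(R: RatingMatrix, fit) -> InfitReport:
    """Person and item infit mean squares for an MSD or Andrich fit.

    Cells whose person or item has no finite measure are excluded; persons
    or items with no usable responses get NaN infit.
    """
    e, v = _cell_moments(fit)
    use = R.observed & np.isfinite(e)
    r = np.nan_to_num(R.ratings)
    sq = np.where(use, (r - np.nan_to_num(e)) ** 2, 0.0)
    vv = np.where(use, np.nan_to_num(v), 0.0)
    pdf_ = use.sum(axis=1).astype(float)
    idf_ = use.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        person_infit = np.where(
            pdf_ > 0, sq.sum(axis=1) / vv.sum(axis=1), np.nan
        )
        item_infit = np.where(idf_ > 0, sq.sum(axis=0) / vv.sum(axis=0), np.nan)

    ok = np.isfinite(person_infit) & (pdf_ > 0)
    vals = np.sort(person_infit[ok])
    dfs = pdf_[ok]
    grid = vals
    emp = np.arange(1, vals.size + 1) / vals.size
    # mixture over persons of the chi2_df / df distribution
    ref = np.mean(
        stats.chi2.cdf(grid[:, None] * dfs[None, :], dfs[None, :]), axis=1
    )
    return InfitReport(
        person_infit=person_infit,
        item_infit=item_infit,
        person_df=pdf_,
        item_df=idf_,
        grid=grid,
        empirical_cdf=emp,
        reference_cdf=ref,
        max_cdf_discrepancy=float(np.max(np.abs(emp - ref))) if vals.size else np.nan,
    )


def probability_curve_data(
    R: RatingMatrix,
    gamma_values: np.ndarray,
    thresholds: np.ndarray,
    model: str = "msd",
    bin_width: float = 0.2,
) -> pd.DataFrame:
    """Observed category frequencies in gamma bins against model curves.

    ``gamma_values`` supplies the person-minus-item difference for every
    cell (shape N x M): true values when replicating the simulation plots,
    estimated values otherwise.  Each observed cell falls in a bin of width
    ``bin_width``; within a bin the observed fraction of each category is
    compared to the model probability at the bin midpoint.

    Returns a tidy frame with columns ``gamma_mid, category, observed,
    predicted, count``; empty bins are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    gamma_values = np.asarray(gamma_values, dtype=float)
    use = R.observed & np.isfinite(gamma_values)
    if not use.any():
        raise ValueError("no observed cells with finite gamma")
    g = gamma_values[use]
    r = R.ratings[use].astype(int)
    L = R.n_thresholds
    bins = np.floor(g / bin_width).astype(int)
    rows = []
    if model == "msd":
        from .model_core import msd_category_probabilities as probfun
    elif model == "andrich":
        from .model_core import andrich_category_probabilities as probfun
    else:
        raise ValueError("model must be 'msd' or 'andrich'")
    for b in np.unique(bins):
        sel = bins == b
        mid = (b + 0.5) * bin_width
        pred = probfun(mid, thresholds)
        cnt = int(sel.sum())
        obs_counts = np.bincount(r[sel], minlength=L + 1)
        for h in range(L + 1):
            rows.append(
                {
                    "gamma_mid": mid,
                    "category": h,
                    "observed": obs_counts[h] / cnt,
                    "predicted": float(pred[h]),
                    "count": cnt,
                }
            )
    return pd.DataFrame(rows)


def curve_discrepancy(curves: pd.DataFrame, min_count: int = 10) -> float:
    """Max |observed - predicted| over bins with at least ``min_count`` obs.

    Sparse bins are excluded: their binomial noise dominates any model
    misfit signal.
    """
    big = curves[curves["count"] >= min_count]
    if big.empty:
        return np.nan
    return float(np.max(np.abs(big["observed"] - big["predicted"])))


def predicted_slope(total_error_variance: float) -> float:
    """Discrimination implied by the error variance: a = pi/sqrt(3 sigma^2).

    The dichotomous Rasch logistic has variance ``sigma^2 = pi^2 / (3 a^2)``
    at discrimination ``a``; inverting it predicts the slope of estimated-
    versus-true measures when the simulation's combined error variance is
    ``sigma^2``.
    """
    if not np.isfinite(total_error_variance) or total_error_variance <= 0:
        raise ValueError("total error variance must be positive")
    return float(np.pi / np.sqrt(3.0 * total_error_variance))
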