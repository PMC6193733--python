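"""The Method of Successive Dichotomizations (MSD).

MSD estimates all parameters of the ordered-threshold rating scale model by
reducing the polytomous problem to L dichotomous ones:

1. For each threshold index h = 1..L build the 0/1 matrix D_h with entry 1
   where the rating is >= h, and fit the dichotomous Rasch model to each
   D_h, giving per-dichotomization person measures b_i(h) and item measures
   d_j(h).
2. Average: the MSD person measure is the mean of b_i(h) over h, the item
   measure the mean of d_j(h); items are re-centred to mean zero.
3. With person and item measures fixed, estimate each threshold tau_h by a
   one-dimensional MLE on D_h.

Because the D_h are nested (an entry equal to 1 at level h is 1 at every
lower level) and every threshold is fit against the same fixed measures,
the estimated thresholds always come out strictly ordered.

Coordinate convention: each dichotomous fit estimates beta_i - tau_h with
items anchored at mean zero, so the averaged person measures carry an
origin of minus the mean threshold, and the threshold estimates are
likewise expressed relative to the mean threshold.  All recovery statistics
in this package are invariant to that common shift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import (
    DegenerateCategoryError,
    DichotomizedMatrix,
    DivergentThresholdError,
    RatingMatrix,
)
from .dichotomous import DichotomousFit, jmle_fit

__all__ = [
    "MSDFit",
    "dichotomize",
    "merge_categories",
    "fit_measures",
    "fit_threshold",
    "fit",
]

logger = logging.getLogger("msdrasch")


@dataclass
class MSDFit:
    """MSD estimates: person/item measures, ordered thresholds, SEs.

    ``per_dichotomization_person`` has shape (L, N) and holds b_i(h), the
    person measure from dichotomization h (NaN where the person's score was
    extreme at that level); similarly ``per_dichotomization_item`` (L, M).
    """

    person_measures: np.ndarray
    item_measures: np.ndarray
    thresholds: np.ndarray
    person_se: np.ndarray
    item_se: np.ndarray
    threshold_se: np.ndarray
    per_dichotomization_person: np.ndarray
    per_dichotomization_item: np.ndarray
    dichotomous_fits: list[DichotomousFit] = field(default_factory=list)
    se_divisor: str = "L"

    @property
    def n_thresholds(self) -> int:
        return self.thresholds.size


def dichotomize(R: RatingMatrix, h: int) -> DichotomizedMatrix:
    """Map ratings to 0/1 at threshold ``h``: 1 iff rating >= h.

    ``h`` runs 1..L; missing entries stay missing.
    """
    if not 1 <= h <= R.n_thresholds:
        raise ValueError(f"threshold index h={h} outside 1..{R.n_thresholds}")
    d = np.where(np.isnan(R.ratings), np.nan, (R.ratings >= h).astype(float))
    return DichotomizedMatrix(
        data=d, level=h, person_ids=R.person_ids, item_ids=R.item_ids
    )


def merge_categories(R: RatingMatrix, q: int) -> RatingMatrix:
    """Merge categories C_{q-1} and C_q by removing threshold ``q``.

    Ratings >= q are decremented; the scale drops to L - 1 thresholds.
    """
    if R.n_thresholds < 2:
        raise ValueError("cannot merge categories of a dichotomous scale")
    if not 1 <= q <= R.n_thresholds:
        raise ValueError(f"threshold index q={q} outside 1..{R.n_thresholds}")
    r = R.ratings.copy()
    obs = ~np.isnan(r)
    r[obs & (r >= q)] -= 1
    return RatingMatrix(
        ratings=r,
        max_category=R.max_category - 1,
        person_ids=R.person_ids,
        item_ids=R.item_ids,
    )


def fit_measures(
    R: RatingMatrix,
    tolerance: float = 1e-6,
    max_iterations: int = 1000,
):
    """Dichotomize L ways, fit each with JMLE, and average the measures.

    Returns ``(person_measures, item_measures, per_h_person, per_h_item,
    fits)`` where the per-dichotomization arrays have shape (L, N) and
    (L, M) with NaN for exclusions.  Final measures are means over the
    dichotomizations where a finite estimate exists; item measures are
    re-centred to mean zero afterwards (the same shift is applied to
    persons so that person-minus-item differences are untouched).
    """
    L = R.n_thresholds
    counts = R.category_counts()
    if np.any(counts == 0):
        unused = np.flatnonzero(counts == 0)
        raise DegenerateCategoryError(
            f"categories {unused.tolist()} are never observed; the "
            "dichotomizations bounding an unused category coincide and its "
            "thresholds cannot be separated"
        )
    per_b = np.full((L, R.n_persons), np.nan)
    per_d = np.full((L, R.n_items), np.nan)
    fits: list[DichotomousFit] = []
    for h in range(1, L + 1):
        below = counts[:h].sum()
        at_or_above = counts[h:].sum()
        if below == 0 or at_or_above == 0:
            raise DegenerateCategoryError(
                f"dichotomization at h={h} is constant: no observed ratings "
                f"{'below' if below == 0 else 'at or above'} category {h}"
            )
        D = dichotomize(R, h)
        f = jmle_fit(D, tolerance=tolerance, max_iterations=max_iterations)
        per_b[h - 1] = f.person_measures
        per_d[h - 1] = f.item_measures
        fits.append(f)
        if f.excluded_persons.size or f.excluded_items.size:
            logger.info(
                "dichotomization h=%d: excluded %d persons, %d items with "
                "extreme scores", h, f.excluded_persons.size,
                f.excluded_items.size,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta = np.nanmean(per_b, axis=0)
        delta = np.nanmean(per_d, axis=0)
    c = np.nanmean(delta)
    delta = delta - c
    beta = beta - c
    return beta, delta, per_b, per_d, fits


def fit_threshold(
    D: DichotomizedMatrix,
    person_measures: np.ndarray,
    item_measures: np.ndarray,
    bounds: tuple[float, float] = (-10.0, 10.0),
    xtol: float = 1e-10,
):
    """Single-parameter MLE of threshold ``tau_h`` with measures fixed.

    Maximizes ``sum d log F(gamma - tau) + (1 - d) log(1 - F(gamma - tau))``
    over ``tau`` alone.  The score function is strictly increasing in
    ``tau``, so the root is found by bracketing (brackets expand beyond
    ``bounds`` if needed).  Returns ``(tau_hat, se)`` with the SE from the
    observed information ``sum p (1 - p)`` at the maximum.
    """
    gamma = np.asarray(person_measures)[:, None] - np.asarray(item_measures)[None, :]
    use = D.observed & np.isfinite(gamma)
    d = D.data[use]
    g = gamma[use]
    if d.size == 0:
        raise DivergentThresholdError("no usable observations for threshold")
    ones = d.sum()
    if ones == 0 or ones == d.size:
        raise DivergentThresholdError(
            f"all responses at level h={D.level} are "
            f"{'0' if ones == 0 else '1'}; the threshold MLE diverges"
        )

    def score(tau):
        return float(ones - expit(g - tau).sum())

    lo, hi = bounds
    while score(lo) > 0 and lo > -50:
        lo *= 2
    while score(hi) < 0 and hi < 50:
        hi *= 2
    if score(lo) > 0 or score(hi) < 0:
        raise DivergentThresholdError(
            f"threshold MLE at level h={D.level} has no finite root"
        )
    tau_hat = brentq(score, lo, hi, xtol=xtol)
    p = expit(g - tau_hat)
    info = float((p * (1.0 - p)).sum())
    return float(tau_hat), 1.0 / np.sqrt(info)


def fit(
    R: RatingMatrix,
    tolerance: float = 1e-6,
    max_iterations: int = 1000,
    se_divisor: str = "L",
) -> MSDFit:
    """Full MSD fit: measures by averaged JMLE, thresholds by 1-D MLE.

    Person SEs follow the successive-dichotomization rule: the standard
    deviation over h of ``b_i(h) - tau_hat_h`` divided by the number of
    dichotomizations the person appears in (``se_divisor="sqrt"`` divides
    by its square root instead); item SEs likewise from ``d_j(h)``.  With a
    single threshold the spread-based rule is undefined and the
    information-based JMLE standard errors are reported instead.
    """
    if se_divisor not in ("L", "sqrt"):
        raise ValueError("se_divisor must be 'L' or 'sqrt'")
    L = R.n_thresholds
    beta, delta, per_b, per_d, fits = fit_measures(
        R, tolerance=tolerance, max_iterations=max_iterations
    )
    tau = np.empty(L)
    tau_se = np.empty(L)
    for h in range(1, L + 1):
        D = dichotomize(R, h)
        tau[h - 1], tau_se[h - 1] = fit_threshold(D, beta, delta)
    if np.any(np.diff(tau) <= 0):  # structurally impossible; guard anyway
        raise RuntimeError("MSD produced disordered thresholds")

    if L == 1:
        warnings.warn(
            "single dichotomization: spread-based standard errors are "
            "undefined; reporting information-based JMLE standard errors",
            stacklevel=2,
        )
        person_se = fits[0].person_se
        item_se = fits[0].item_se
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            n_eff_p = np.sum(np.isfinite(per_b), axis=0).astype(float)
            n_eff_i = np.sum(np.isfinite(per_d), axis=0).astype(float)
            sd_p = np.nanstd(per_b - tau[:, None], axis=0, ddof=1)
            sd_i = np.nanstd(per_d, axis=0, ddof=1)
        div_p = n_eff_p if se_divisor == "L" else np.sqrt(n_eff_p)
        div_i = n_eff_i if se_divisor == "L" else np.sqrt(n_eff_i)
        with np.errstate(divide="ignore", invalid="ignore"):
            person_se = sd_p / div_p
            item_se = sd_i / div_i
        # persons/items seen in a single dichotomization: fall back to the
        # information-based SE from that fit
        single_p = n_eff_p == 1
        single_i = n_eff_i == 1
        if single_p.any() or single_i.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                info_p = np.nanmean(
                    np.vstack([f.person_se for f in fits]), axis=0
                )
                info_i = np.nanmean(
                    np.vstack([f.item_se for f in fits]), axis=0
                )
            person_se = np.where(single_p, info_p, person_se)
            item_se = np.where(single_i, info_i, item_se)

    return MSDFit(
        person_measures=beta,
        item_measures=delta,
        thresholds=tau,
        person_se=person_se,
        item_se=item_se,
        threshold_se=tau_se,
        per_dichotomization_person=per_b,
        per_dichotomization_item=per_d,
        dichotomous_fits=fits,
        se_divisor=se_divisor,
    )
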