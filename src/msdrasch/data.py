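"""Core data containers for rating-scale matrices.

A rating matrix holds ordinal responses of ``N`` persons to ``M`` items,
each response an integer category ``0..L`` (``L`` = number of thresholds,
``L + 1`` = number of rating categories).  Missing responses are stored as
NaN in a float array so that masking stays cheap and vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RatingMatrix",
    "DichotomizedMatrix",
    "ThresholdOrderError",
    "DegenerateDataError",
    "DegenerateCategoryError",
    "ConvergenceError",
    "DivergentThresholdError",
    "UndefinedCorrelationError",
]


class ThresholdOrderError(ValueError):
    """Thresholds violate the strict ordering the model requires."""


class DegenerateDataError(ValueError):
    """The data carry no information about the requested parameters."""


class DegenerateCategoryError(DegenerateDataError):
    """A rating category is unused, making its threshold inestimable."""


class ConvergenceError(RuntimeError):
    """Iterative estimation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class DivergentThresholdError(RuntimeError):
    """A threshold MLE diverges to +/- infinity (one-sided responses)."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested against a constant vector."""


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{k + 1}" for k in range(n)]


@dataclass
class RatingMatrix:
    """N x M integer ratings in ``0..max_category`` with NaN for missing.

    Parameters
    ----------
    ratings
        Float array of shape (n_persons, n_items); observed entries must be
        integral and lie in ``[0, max_category]``, missing entries are NaN.
    max_category
        The top category label ``L``; the scale has ``L + 1`` categories and
        ``L`` thresholds.  If None, inferred as the maximum observed rating.
    """

    ratings: np.ndarray
    max_category: int | None = None
    person_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        r = np.asarray(self.ratings, dtype=float)
        if r.ndim != 2:
            raise ValueError("ratings must be a 2-D array")
        obs = ~np.isnan(r)
        vals = r[obs]
        if vals.size and not np.all(vals == np.round(vals)):
            bad = np.argwhere(obs & (r != np.round(r)))[0]
            raise ValueError(
                f"non-integer rating at row {bad[0]}, column {bad[1]}"
            )
        if vals.size and vals.min() < 0:
            raise ValueError("negative ratings are not valid categories")
        if self.max_category is None:
            if not vals.size:
                raise ValueError("cannot infer max_category from empty data")
            self.max_category = int(vals.max())
        if vals.size and vals.max() > self.max_category:
            raise ValueError(
                f"rating {int(vals.max())} exceeds max_category="
                f"{self.max_category}"
            )
        if self.max_category < 1:
            raise ValueError("need at least two categories (max_category >= 1)")
        self.ratings = r
        if not self.person_ids:
            self.person_ids = _default_ids("P", r.shape[0])
        if not self.item_ids:
            self.item_ids = _default_ids("I", r.shape[1])

    @property
    def n_persons(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_items(self) -> int:
        return self.ratings.shape[1]

    @property
    def n_thresholds(self) -> int:
        """Number of thresholds L (= max_category)."""
        return int(self.max_category)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.ratings)

    def category_counts(self) -> np.ndarray:
        """Count of observed responses in each category 0..L."""
        vals = self.ratings[self.observed].astype(int)
        return np.bincount(vals, minlength=self.max_category + 1)


@dataclass
class DichotomizedMatrix:
    """0/1 matrix D_h obtained by thresholding ratings at category ``h``.

    Entry (i, j) is 1 when the source rating r_ij >= h, 0 when r_ij < h,
    NaN when missing; the missing pattern equals the source matrix's.
    """

    data: np.ndarray
    level: int
    person_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        obs = ~np.isnan(d)
        if not np.all(np.isin(d[obs], (0.0, 1.0))):
            raise ValueError("dichotomized entries must be 0, 1 or NaN")
        self.data = d
        if not self.person_ids:
            self.person_ids = _default_ids("P", d.shape[0])
        if not self.item_ids:
            self.item_ids = _default_ids("I", d.shape[1])

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.data)
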