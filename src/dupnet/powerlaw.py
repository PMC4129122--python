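"""Power-law fitting of duplicability distributions.

The number of genes P(K) with K duplicates typically decays as a power law
P(K) ∝ K^-alpha; on a log-log plot this is a straight line with slope
-alpha. A distribution is represented as a plain mapping ``{K: value}``
with integer K >= 1 and strictly positive values (zero-count K are omitted
because their logarithm is undefined). Values may be raw counts or
percentages — alpha is invariant under uniform rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import AlignmentError, InsufficientDataError
from .stats import ols_loglog

__all__ = [
    "PowerLawFit",
    "fit_power_law",
    "overlay_shift",
    "restrict_to_k_values",
    "normalize_distribution",
]

#: A P(K) histogram: K (int >= 1) -> count or percentage (> 0).
PKDistribution = Mapping[int, float]


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float        # negated log-log slope; positive for a decaying law
    intercept: float    # log10 intercept
    r_squared: float
    n_points: int

    def predict(self, k: int) -> float:
        """P(K) predicted by the fitted line (on the original scale)."""
        return 10.0 ** (self.intercept - self.alpha * math.log10(k))


def _validated(dist: PKDistribution) -> dict[int, float]:
    out = {}
    for k, v in dist.items():
        if k < 1:
            raise ValueError(f"K values must be >= 1, got {k}")
        if v <= 0:
            raise ValueError(f"P(K) values must be > 0, got {v} at K={k}")
        out[int(k)] = float(v)
    return out


def fit_power_law(dist: PKDistribution) -> PowerLawFit:
    """Unweighted OLS of log10 P(K) on log10 K over every point of ``dist``."""
    d = _validated(dist)
    if len(d) < 2:
        raise InsufficientDataError("power-law fit needs at least 2 distinct K values")
    slope, intercept, r2 = ols_loglog(sorted(d.items()))
    return PowerLawFit(alpha=-slope, intercept=intercept, r_squared=r2, n_points=len(d))


def overlay_shift(dist: PKDistribution, reference: PKDistribution) -> dict[int, float]:
    """Vertically rescale ``dist`` so its leftmost point overlaps ``reference``.

    Used to compare the shapes of two P(K) curves: multiplying every value by
    reference(K_min)/dist(K_min) translates the curve in log space without
    changing its slope.
    """
    d = _validated(dist)
    ref = _validated(reference)
    k_min = min(d)
    if min(ref) != k_min:
        raise AlignmentError(
            f"distributions do not share their smallest K ({k_min} vs {min(ref)})"
        )
    factor = ref[k_min] / d[k_min]
    return {k: v * factor for k, v in d.items()}


def restrict_to_k_values(dist: PKDistribution, allowed: Iterable[int]) -> dict[int, float]:
    """Restrict a distribution to the K values in ``allowed``.

    This makes a background curve comparable with a small focal group that
    spans only a few K values (both curves then have identical supports).
    """
    allowed = set(allowed)
    if not allowed:
        raise InsufficientDataError("allowed K set is empty")
    d = _validated(dist)
    out = {k: v for k, v in d.items() if k in allowed}
    if not out:
        raise InsufficientDataError("no K value of the distribution is in the allowed set")
    return out


def normalize_distribution(dist: PKDistribution) -> dict[int, float]:
    """Rescale values to percentages summing to 100."""
    d = _validated(dist)
    total = sum(d.values())
    return {k: 100.0 * v / total for k, v in d.items()}
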