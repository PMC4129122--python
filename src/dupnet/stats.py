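"""Shared statistics used by the analysis stages.

All routines delegate the numerics to scipy/numpy; this module fixes the
conventions the pipeline relies on (no continuity correction by default,
base-10 logs, add-one empirical p-values, linearly interpolated quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, UntestableError

__all__ = [
    "Chi2Result",
    "pearson_chi2",
    "pearson_correlation",
    "ols_loglog",
    "empirical_p",
    "five_number_summary",
]


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float


def pearson_chi2(table: Sequence[Sequence[float]], correction: bool = False) -> Chi2Result:
    """Pearson chi-square test of independence on a table of raw counts.

    No Yates continuity correction by default (``correction=True`` to enable).
    Raises :class:`UntestableError` on a zero row or column margin.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise UntestableError("contingency table has a zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=correction)
    return Chi2Result(float(stat), int(df), float(p))


def pearson_correlation(x: Sequence[float], y: Sequence[float]):
    """Product-moment correlation with a two-sided t-test p-value.

    Returns ``(r, p)``, or ``None`` when either input has zero variance
    (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bin_correlation(x: Sequence[float], y: Sequence[float]):
    """Pearson correlation tolerant of two-point binned summaries.

    With exactly two points the correlation is ±1 by definition (p-value
    undefined, returned as None); zero variance returns None. Otherwise
    identical to :func:`pearson_correlation`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if x.size == 2:
        r = 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
        return r, None
    return pearson_correlation(x, y)


def ols_loglog(points: Sequence[tuple[float, float]]):
    """Ordinary least squares of log10(y) on log10(x).

    Returns ``(slope, intercept, r_squared)``. Coordinates must be strictly
    positive; at least two distinct x values are required.
    """
    pts = list(points)
    if any(x <= 0 or y <= 0 for x, y in pts):
        raise ValueError("log-log regression requires strictly positive coordinates")
    xs = np.log10([x for x, _ in pts])
    ys = np.log10([y for _, y in pts])
    if np.unique(xs).size < 2:
        raise InsufficientDataError("need at least 2 distinct x values")
    if np.ptp(ys) == 0:
        # constant y: the flat line fits exactly (R^2 conventionally 0/0)
        return 0.0, float(ys[0]), 1.0
    res = sps.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def empirical_p(observed: float, null: Sequence[float], direction: str = "ge") -> float:
    """Add-one empirical p-value of ``observed`` against a null sample.

    ``direction="ge"`` counts null values >= observed (upper tail),
    ``"le"`` the lower tail. The add-one (permutation-style) estimator
    (#beyond + 1) / (n + 1) never returns 0 at finite sample size.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise InsufficientDataError("null sample is empty")
    if direction == "ge":
        beyond = int(np.sum(null >= observed))
    elif direction == "le":
        beyond = int(np.sum(null <= observed))
    else:
        raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
    return (beyond + 1) / (null.size + 1)


def five_number_summary(values: Sequence[float]):
    """(min, Q1, median, Q3, max) with linearly interpolated quartiles."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("cannot summarize an empty sample")
    q = np.percentile(vals, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(v) for v in q)
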