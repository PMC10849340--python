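"""Exponential growth-constant estimation from OD600 plate-reader series.

Growth curves are log-transformed, truncated to the linear (exponential)
range, and fit with ordinary least squares; rates are natural-log constants
per hour.  The linear range is operationalized as the longest contiguous
window whose blank-subtracted OD lies within configured bounds and whose
log-linear fit reaches a minimum R^2.  Group comparisons use Welch's
two-sample t-test (switchable to pooled variance).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import (
    NoLinearRangeError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "FitConfig",
    "fit_exponential_rate",
    "compare_rates",
    "correlate_validation",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one well/culture; times in minutes."""

    curve_id: str
    times_min: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "od600", od)
        if t.ndim != 1 or t.shape != od.shape:
            raise ValidationError("times and OD must be 1-D and equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(od))):
            raise ValidationError("times and OD must be finite")


@dataclass(frozen=True)
class GrowthFit:
    """Result of a log-linear fit: rate per hour (natural log) and window."""

    curve_id: str
    rate: float
    intercept: float  # ln OD at t = 0
    window: tuple[int, int]  # [start, stop) indices into the curve
    r_squared: float
    n_points: int

    def doublings_per_hour(self) -> float:
        """Reporting-layer conversion of the base-e constant."""
        return self.rate / np.log(2.0)


@dataclass(frozen=True)
class FitConfig:
    """Linear-range selection rule and blank handling.

    ``blank`` is subtracted from every OD reading before log transform
    (default 0: fit raw OD).  A window qualifies if all its blank-subtracted
    ODs are inside ``[od_min, od_max]``, it has at least ``min_points``
    samples, and its log-linear R^2 is >= ``r2_min``; the longest
    qualifying contiguous window wins (ties: higher R^2).
    """

    blank: float = 0.0
    od_min: float = 0.02
    od_max: float = 0.5
    r2_min: float = 0.99
    min_points: int = 9


def _ols_loglinear(t_h: np.ndarray, ln_od: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t_h, ln_od)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_exponential_rate(curve: GrowthCurve, cfg: FitConfig | None = None) -> GrowthFit:
    """Fit the exponential growth constant of one OD600 curve.

    Raises
    ------
    NoLinearRangeError
        If no contiguous window satisfies the selection rule.
    """
    cfg = cfg or FitConfig()
    if len(curve.times_min) < 8:
        raise ValidationError("need >= 8 points to attempt a fit")
    od = curve.od600 - cfg.blank
    t_h = curve.times_min / 60.0
    in_range = (od >= cfg.od_min) & (od <= cfg.od_max) & (od > 0)

    best: tuple[int, float, int, int, float, float] | None = None
    # enumerate contiguous in-range runs, then sub-windows longest-first
    i = 0
    n = len(od)
    while i < n:
        if not in_range[i]:
            i += 1
            continue
        j = i
        while j < n and in_range[j]:
            j += 1
        run_len = j - i
        if run_len >= cfg.min_points:
            ln_od = np.log(od[i:j])
            tt = t_h[i:j]
            for length in range(run_len, cfg.min_points - 1, -1):
                cand = None
                for s in range(0, run_len - length + 1):
                    slope, icept, r2 = _ols_loglinear(
                        tt[s : s + length], ln_od[s : s + length]
                    )
                    if np.isfinite(r2) and r2 >= cfg.r2_min:
                        if cand is None or r2 > cand[1]:
                            cand = (length, r2, i + s, i + s + length, slope, icept)
                if cand is not None:
                    if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                        best = cand
                    break  # shorter windows in this run cannot be longer
        i = j
    if best is None:
        raise NoLinearRangeError(
            f"curve {curve.curve_id!r}: no contiguous window of >= "
            f"{cfg.min_points} points with OD in [{cfg.od_min}, {cfg.od_max}] "
            f"and R^2 >= {cfg.r2_min}"
        )
    length, r2, s, e, slope, icept = best
    return GrowthFit(
        curve_id=curve.curve_id,
        rate=slope,
        intercept=icept,
        window=(s, e),
        r_squared=r2,
        n_points=length,
    )


def compare_rates(
    group_a: Sequence[float],
    group_b: Sequence[float],
    tails: int = 2,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test between growth-rate groups.

    Welch's unequal-variance statistic by default.  One-tailed tests the
    direction ``group_a > group_b``.  Returns ``(t, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if tails not in (1, 2):
        raise ValidationError("tails must be 1 or 2")
    # treat numerically-constant groups as zero-variance (float summation of
    # identical values can leave an O(eps) residual)
    zero_a = a.std(ddof=1) <= 1e-12 * max(abs(a.mean()), 1e-30)
    zero_b = b.std(ddof=1) <= 1e-12 * max(abs(b.mean()), 1e-30)
    if zero_a and zero_b:
        if np.isclose(a.mean(), b.mean(), rtol=1e-12, atol=0.0):
            return 0.0, 1.0
        # perfectly separated constants: degenerate but unambiguous
        t = np.inf if a.mean() > b.mean() else -np.inf
        if tails == 2:
            return t, 0.0
        return t, 0.0 if t > 0 else 1.0
    alternative = "greater" if tails == 1 else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def correlate_validation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between two rate/metric vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 3:
        raise ValidationError("need equal-length 1-D vectors with n >= 3")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("inputs must be finite")
    if xa.std() == 0 or ya.std() == 0:
        raise UndefinedCorrelationError("zero variance; correlation undefined")
    return float(stats.pearsonr(xa, ya).statistic)
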