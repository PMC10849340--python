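"""Deterministic two-state model of mtDNA loss in a growing cell population.

A population of respiration-competent (rho+) cells grows exponentially with
growth constant ``g_wt`` (per hour, natural log) and converts to
respiration-deficient rho0 cells at a constant per-cell rate ``r``; rho0
cells grow with their own constant ``g_mut``.  Conversion changes the state
of a cell rather than killing it, so the instantaneous per-capita growth
rate of the whole population is always the mutant-fraction-weighted average
of the two growth constants.

The governing ODE system is::

    dP_wt/dt  = (g_wt - r) * P_wt
    dP_mut/dt = g_mut * P_mut + r * P_wt

whose closed-form solution (with a = g_wt - r, b = g_mut) is::

    P_wt(t)  = P_wt0 * exp(a t)
    P_mut(t) = P_mut0 * exp(b t) + r * P_wt0 * (exp(a t) - exp(b t)) / (a - b)

with the degenerate branch ``P_mut0*exp(b t) + r*P_wt0*t*exp(b t)`` when
``a == b``.  When ``g_wt - r > g_mut`` the mutant fraction converges to the
finite equilibrium ``f* = r / (g_wt - g_mut)`` (coexistence); otherwise the
mutant fixes (``f* = 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import UndefinedFractionError, ValidationError

__all__ = [
    "TwoStateParams",
    "PopulationTrajectory",
    "Regime",
    "RegimeLabel",
    "solve_closed_form",
    "mutant_fraction_at",
    "equilibrium_fraction",
    "population_growth_rate",
    "classify_regime",
    "sweep_fraction_grid",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Model parameters.

    Parameters
    ----------
    g_wt
        Exponential growth constant of rho+ cells (per hour, natural log).
    g_mut
        Exponential growth constant of rho0 cells (per hour).
    r
        mtDNA loss (rho+ -> rho0 conversion) rate per rho+ cell per hour.
    p_wt0, p_mut0
        Initial abundances (dimensionless cell counts, >= 0; at least one
        must be positive).
    """

    g_wt: float
    g_mut: float
    r: float
    p_wt0: float = 1.0
    p_mut0: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.g_wt, self.g_mut, self.r, self.p_wt0, self.p_mut0)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError("all model parameters must be finite")
        if self.r < 0:
            raise ValidationError(f"loss rate r must be >= 0, got {self.r}")
        if self.p_wt0 < 0 or self.p_mut0 < 0:
            raise ValidationError("initial abundances must be >= 0")
        if self.p_wt0 + self.p_mut0 <= 0:
            raise ValidationError("initial total abundance must be positive")

    def with_initial_fraction(self, f0: float, total: float = 1.0) -> "TwoStateParams":
        """Same rates, initial state split as a mutant fraction ``f0`` of ``total``."""
        if not 0 <= f0 <= 1:
            raise ValidationError(f"initial fraction must be in [0, 1], got {f0}")
        return replace(self, p_wt0=total * (1.0 - f0), p_mut0=total * f0)


@dataclass(frozen=True)
class PopulationTrajectory:
    """Time-indexed abundances of the two subpopulations and the mutant fraction."""

    times: np.ndarray
    p_wt: np.ndarray
    p_mut: np.ndarray
    f: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "p_wt", np.asarray(self.p_wt, dtype=float))
        object.__setattr__(self, "p_mut", np.asarray(self.p_mut, dtype=float))
        if self.f is None:
            total = self.p_wt + self.p_mut
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(total > 0, self.p_mut / total, np.nan)
            object.__setattr__(self, "f", frac)
        else:
            object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        n = len(self.times)
        if not (len(self.p_wt) == len(self.p_mut) == len(self.f) == n):
            raise ValidationError("trajectory arrays must have equal length")


class Regime(str, Enum):
    FIXATION = "FIXATION"
    COEXISTENCE = "COEXISTENCE"


@dataclass(frozen=True)
class RegimeLabel:
    """Long-run behavior: regime, equilibrium mutant fraction, per-capita rate."""

    regime: Regime
    f_star: float
    long_run_growth_rate: float


def _validate_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim == 0:
        t = t[None]
    if not np.all(np.isfinite(t)):
        raise ValidationError("times must be finite")
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    return t


def _expm1_over_x(x: np.ndarray) -> np.ndarray:
    """(exp(x) - 1) / x with the removable singularity filled by its series."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-9
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 + x / 2.0 + x * x / 6.0, np.expm1(safe) / safe)
    return out


def _components_scaled(params: TwoStateParams, t: np.ndarray, shift: float):
    """P_wt(t)*exp(-shift*t) and P_mut(t)*exp(-shift*t), overflow-safe for
    any ``shift >= max(a, b)``.

    The conversion kernel (exp(a t) - exp(b t))/(a - b) is evaluated as
    t * exp((b - shift) t) * expm1((a-b) t)/((a-b) t) only where |a-b|t is
    small (cancellation region); elsewhere the direct difference of the two
    shifted exponentials is exact and cannot overflow.
    """
    a = params.g_wt - params.r
    b = params.g_mut
    gap = a - b
    wt = params.p_wt0 * np.exp((a - shift) * t)
    x = gap * t
    small = np.abs(x) < 1e-6
    ea = np.exp((a - shift) * t)
    eb = np.exp((b - shift) * t)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        direct = np.where(small, 0.0, (ea - eb) / np.where(small, 1.0, gap))
        series = t * eb * _expm1_over_x(x)
        kernel = np.where(small, series, direct)
    mut = params.p_mut0 * eb + params.r * params.p_wt0 * kernel
    return wt, mut


def solve_closed_form(
    params: TwoStateParams, times: Sequence[float]
) -> PopulationTrajectory:
    """Evaluate the closed-form solution of the two-state ODE system.

    Handles the degenerate branch ``g_wt - r == g_mut`` (and its numerical
    neighborhood) via an expm1-based kernel to avoid catastrophic
    cancellation.

    Raises
    ------
    ValidationError
        If any time is negative or non-finite.
    """
    t = _validate_times(times)
    p_wt, p_mut = _components_scaled(params, t, shift=0.0)
    return PopulationTrajectory(times=t, p_wt=p_wt, p_mut=p_mut)


def mutant_fraction_at(params: TwoStateParams, t) -> np.ndarray | float:
    """Mutant (rho0) fraction f(t) = P_mut / (P_wt + P_mut), overflow-safe.

    Accepts a scalar time or an array; returns the matching shape.
    """
    scalar = np.isscalar(t) or (isinstance(t, np.ndarray) and t.ndim == 0)
    tt = _validate_times(t)
    shift = max(params.g_wt - params.r, params.g_mut, 0.0)
    wt, mut = _components_scaled(params, tt, shift=shift)
    total = wt + mut
    if np.any(total <= 0):
        raise UndefinedFractionError(
            "total abundance is zero (or underflowed); fraction undefined"
        )
    f = np.clip(mut / total, 0.0, 1.0)
    return float(f[0]) if scalar else f


def equilibrium_fraction(params: TwoStateParams) -> float:
    """Long-run mutant fraction f*.

    ``r / (g_wt - g_mut)`` under coexistence (``g_wt - r > g_mut``), else 1.
    The boundary ``g_wt - r == g_mut`` has no finite equilibrium and is
    classified with the fixation branch (strict inequality).
    """
    if params.g_wt - params.r > params.g_mut:
        if params.r == 0:
            return 0.0
        return params.r / (params.g_wt - params.g_mut)
    return 1.0


def population_growth_rate(params: TwoStateParams, t) -> np.ndarray | float:
    """Instantaneous per-capita growth rate of the total population at ``t``.

    Because conversion conserves cells, this is exactly the weighted average
    ``(1 - f(t))*g_wt + f(t)*g_mut`` at every time, converging to
    ``max(g_wt - r, g_mut)`` in the long run.
    """
    f = mutant_fraction_at(params, t)
    return (1.0 - f) * params.g_wt + f * params.g_mut


def classify_regime(params: TwoStateParams) -> RegimeLabel:
    """COEXISTENCE iff ``g_wt - r > g_mut`` (strict); otherwise FIXATION."""
    f_star = equilibrium_fraction(params)
    if params.g_wt - params.r > params.g_mut:
        regime = Regime.COEXISTENCE
        rate = (1.0 - f_star) * params.g_wt + f_star * params.g_mut
    else:
        regime = Regime.FIXATION
        rate = params.g_mut
    return RegimeLabel(regime=regime, f_star=f_star, long_run_growth_rate=rate)


def sweep_fraction_grid(
    base: TwoStateParams,
    vary: str,
    values: Sequence[float],
    times: Sequence[float],
) -> np.ndarray:
    """Mutant fraction f(t) over a parameter grid.

    Parameters
    ----------
    vary
        ``"r"`` or ``"g_mut"``: which parameter the rows scan.
    values
        Grid values for the varied parameter.
    times
        Evaluation times (columns).

    Returns
    -------
    ndarray of shape ``(len(values), len(times))``.
    """
    if vary not in ("r", "g_mut"):
        raise ValidationError(f"vary must be 'r' or 'g_mut', got {vary!r}")
    t = _validate_times(times)
    vals = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("grid values must be finite")
    out = np.empty((len(vals), len(t)))
    for i, v in enumerate(vals):
        p = replace(base, **{vary: float(v)})
        out[i] = np.atleast_1d(mutant_fraction_at(p, t))
    return out
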