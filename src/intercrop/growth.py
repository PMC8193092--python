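"""Three-parameter logistic accumulation model and derived rate quantities.

Cumulative above-ground biomass (g per individual) or nutrient uptake
(mg N or P per individual) over the growing season is described by

    NU(t) = NU_max / (1 + exp(r * (t_max - t)))

where ``NU_max`` is the asymptotic cumulative amount, ``r`` (week^-1) the
relative accumulation rate and ``t_max`` (weeks after seedling emergence)
the inflection point — the week of the fastest instantaneous accumulation.
The instantaneous rate is the time derivative

    dNU/dt = r * NU(t) * (1 - NU(t) / NU_max)

which is unimodal with its maximum I_max = r * NU_max / 4 attained at
t = t_max.  These three quantities (asymptote, steepness, peak-rate timing)
are the currency of the temporal-niche comparisons elsewhere in the package.

All time arguments are in weeks.  ``r`` is kept per-week throughout;
multiply by :data:`PER_WEEK_TO_PER_DAY` to report daily rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "LogisticParams",
    "PeakRate",
    "logistic_value",
    "instantaneous_rate",
    "peak_rate",
    "PER_WEEK_TO_PER_DAY",
]

#: Convert a per-week rate to a per-day rate for reporting.
PER_WEEK_TO_PER_DAY = 1.0 / 7.0


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of one logistic accumulation trajectory.

    Attributes
    ----------
    nu_max : float
        Maximum cumulative uptake/biomass (mg for N and P, g for biomass,
        per individual).  Strictly positive.
    r : float
        Relative accumulation rate, per week.  Strictly positive.
    t_max : float
        Week of the maximum instantaneous rate (inflection point).  Finite.
    """

    nu_max: float
    r: float
    t_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.nu_max) and self.nu_max > 0):
            raise ValueError(f"nu_max must be finite and > 0, got {self.nu_max!r}")
        if not (np.isfinite(self.r) and self.r > 0):
            raise ValueError(f"r must be finite and > 0, got {self.r!r}")
        if not np.isfinite(self.t_max):
            raise ValueError(f"t_max must be finite, got {self.t_max!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.nu_max, self.r, self.t_max], dtype=float)


@dataclass(frozen=True)
class PeakRate:
    """Maximum instantaneous accumulation rate and when it occurs."""

    i_max: float       # g/week or mg/week per individual
    t_at_peak: float   # weeks after emergence


def logistic_value(params: LogisticParams, t):
    """Cumulative amount NU(t) at week(s) ``t``.

    Computed as ``nu_max * expit(r * (t - t_max))``; ``expit`` saturates
    gracefully so arguments far beyond +/-700 return exactly 0 or nu_max
    without overflow.
    """
    t = np.asarray(t, dtype=float)
    out = params.nu_max * expit(params.r * (t - params.t_max))
    return out if out.ndim else float(out)


def instantaneous_rate(params: LogisticParams, t):
    """Instantaneous accumulation rate dNU/dt at week(s) ``t``.

    Equals ``r * NU(t) * (1 - NU(t)/nu_max)``; non-negative and unimodal
    with mode at ``t_max``.
    """
    t = np.asarray(t, dtype=float)
    p = expit(params.r * (t - params.t_max))
    out = params.r * params.nu_max * p * (1.0 - p)
    return out if out.ndim else float(out)


def peak_rate(params: LogisticParams) -> PeakRate:
    """Peak instantaneous rate I_max = r * nu_max / 4, attained at t_max."""
    return PeakRate(i_max=params.r * params.nu_max / 4.0, t_at_peak=params.t_max)
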