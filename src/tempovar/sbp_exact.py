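"""Closed-form statistics of the simple birth (Yule) process.

In the simple birth process each of the ``n`` individuals in a population
divides independently at per-capita rate ``mu``, so the total division rate
is ``mu * n``.  Starting from an inoculum of ``n0`` individuals, the
abundance distribution at time ``t`` is a shifted negative binomial, and the
time at which the population first reaches a threshold ``omega`` (the
first-passage time, FPT) is a sum of independent exponential waiting times
``Exp(mu * n)`` for ``n = n0 .. omega - 1``.  This module provides the
abundance law, the FPT density, and the FPT moments — in particular the
temporal standard deviation (TSD), the standard deviation of threshold-
crossing times across replicate populations, which asymptotes to
``1 / (mu * sqrt(n0))`` for large thresholds.

All rates are per hour and all times in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import special, stats

__all__ = [
    "GrowthParams",
    "PassageProblem",
    "FptMoments",
    "abundance_pmf",
    "abundance_moments",
    "reaction_probability",
    "fpt_density",
    "fpt_moments",
    "tsd_asymptotic",
]

#: below this threshold partial sums are formed directly (transparent path);
#: above it, digamma/trigamma differences give the same result in O(1).
_DIRECT_SUM_LIMIT = 1000


@dataclass(frozen=True)
class GrowthParams:
    """Per-capita division rate of an exponentially growing population.

    Parameters
    ----------
    mu : float
        Per-capita division rate in 1/hour; must be strictly positive.
    """

    mu: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")

    def division_time(self) -> float:
        """Population doubling time ln(2)/mu, in hours."""
        return math.log(2.0) / self.mu


@dataclass(frozen=True)
class PassageProblem:
    """A first-passage question: inoculum ``n0`` growing to threshold ``omega``.

    Requires ``1 <= n0 < omega`` (both integer individual counts).
    """

    n0: int
    omega: int

    def __post_init__(self) -> None:
        if int(self.n0) != self.n0 or int(self.omega) != self.omega:
            raise ValueError("n0 and omega must be integers")
        if not (1 <= self.n0 < self.omega):
            raise ValueError(
                f"need 1 <= n0 < omega, got n0={self.n0}, omega={self.omega}"
            )


class FptMoments(NamedTuple):
    mean: float  # hours
    variance: float  # hours^2
    tsd: float  # hours


def _validate_time(t: float) -> float:
    t = float(t)
    if not (np.isfinite(t) and t >= 0):
        raise ValueError(f"time must be non-negative and finite, got {t}")
    return t


def abundance_pmf(params: GrowthParams, n0: int, t, n):
    """P(population = n at time t | inoculum n0) for the simple birth process.

    The law is a negative binomial shifted by the inoculum:
    ``C(n-1, n0-1) * exp(-mu*n0*t) * (1 - exp(-mu*t))**(n - n0)``.
    Evaluated in log space so large ``n`` does not overflow.  Exactly zero
    for ``n < n0`` (a pure birth process cannot shrink).

    ``t`` must be a scalar; ``n`` may be an array.
    """
    if int(n0) != n0 or n0 < 1:
        raise ValueError(f"n0 must be an integer >= 1, got {n0}")
    t = _validate_time(t)
    n_arr = np.asarray(n)
    scalar = n_arr.ndim == 0
    n_arr = np.atleast_1d(n_arr).astype(np.int64)
    out = np.zeros(n_arr.shape, dtype=float)
    valid = n_arr >= n0
    if t == 0.0:
        out[n_arr == n0] = 1.0
    elif np.any(valid):
        nv = n_arr[valid].astype(float)
        mu = params.mu
        # log(1 - e^{-mu t}) via expm1 for accuracy at small mu*t
        log_q = np.log(-np.expm1(-mu * t))
        log_pmf = (
            special.gammaln(nv)
            - special.gammaln(n0)
            - special.gammaln(nv - n0 + 1)
            - mu * n0 * t
            + (nv - n0) * log_q
        )
        out[valid] = np.exp(log_pmf)
    return float(out[0]) if scalar else out


def abundance_moments(params: GrowthParams, n0: int, t: float) -> tuple[float, float]:
    """Mean and variance of the abundance at time ``t``.

    mean = n0 * e^{mu t};  variance = n0 * e^{mu t} * (e^{mu t} - 1).
    """
    if n0 < 1:
        raise ValueError(f"n0 must be >= 1, got {n0}")
    t = _validate_time(t)
    g = math.exp(params.mu * t)
    return n0 * g, n0 * g * (g - 1.0)


def reaction_probability(params: GrowthParams, problem: PassageProblem, t) -> float:
    """Probability the population has reached ``omega`` by time ``t``.

    Equals ``1 - sum_{i=n0}^{omega-1} P_t(i | n0)`` and also the CDF of the
    first-passage time.  Computed through the negative-binomial survival
    function (N(t) - n0 is NB(n0, e^{-mu t})), which is the regularized
    incomplete beta function — exact for arbitrarily large ``omega``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p = np.exp(-params.mu * t)
    out = stats.nbinom.sf(problem.omega - problem.n0 - 1, problem.n0, p)
    return float(out) if out.ndim == 0 else out


def fpt_density(params: GrowthParams, problem: PassageProblem, t):
    """Density (1/hour) of the first-passage time at threshold ``omega``.

    ``mu * (omega - n0) * C(omega-1, n0-1) * e^{-mu n0 t}
    * (1 - e^{-mu t})**(omega - n0 - 1)``, evaluated via log-gamma
    arithmetic.  Integrates to one over [0, inf).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    mu, n0, omega = params.mu, problem.n0, problem.omega
    log_pref = (
        math.log(mu)
        + math.log(omega - n0)
        + special.gammaln(omega)
        - special.gammaln(n0)
        - special.gammaln(omega - n0 + 1)
    )
    out = np.zeros(t_arr.shape, dtype=float)
    pos = t_arr > 0
    with np.errstate(divide="ignore"):
        log_q = np.log(-np.expm1(-mu * t_arr[pos]))
    out[pos] = np.exp(
        log_pref - mu * n0 * t_arr[pos] + (omega - n0 - 1) * log_q
    )
    if np.any(~pos):  # t = 0: density is mu*n0 when omega = n0 + 1, else 0
        out[~pos] = mu * n0 if omega == n0 + 1 else 0.0
    return float(out[0]) if scalar else out


def _harmonic_partial(n0: int, omega: int) -> float:
    """sum_{n=n0}^{omega-1} 1/n, via digamma difference for large omega."""
    if omega <= _DIRECT_SUM_LIMIT:
        return float(np.sum(1.0 / np.arange(n0, omega, dtype=float)))
    return float(special.digamma(omega) - special.digamma(n0))


def _inverse_square_partial(n0: int, omega: int) -> float:
    """sum_{n=n0}^{omega-1} 1/n^2, via trigamma difference for large omega."""
    if omega <= _DIRECT_SUM_LIMIT:
        return float(np.sum(1.0 / np.arange(n0, omega, dtype=float) ** 2))
    return float(special.polygamma(1, n0) - special.polygamma(1, omega))


def fpt_moments(params: GrowthParams, problem: PassageProblem) -> FptMoments:
    """Mean, variance, and TSD of the first-passage time.

    The FPT is a sum of independent waiting times ``Exp(mu * n)``, so

    * mean = (1/mu) * sum_{n=n0}^{omega-1} 1/n
    * variance = (1/mu^2) * sum_{n=n0}^{omega-1} 1/n^2

    Partial sums are formed as polygamma differences above omega = 1000,
    so thresholds up to 1e8 and beyond are exact and O(1).
    """
    mu = params.mu
    mean = _harmonic_partial(problem.n0, problem.omega) / mu
    var = _inverse_square_partial(problem.n0, problem.omega) / mu**2
    return FptMoments(mean=mean, variance=var, tsd=math.sqrt(var))


def tsd_asymptotic(params: GrowthParams, n0: int) -> float:
    """Large-threshold limit of the TSD: ``1 / (mu * sqrt(n0))``."""
    if n0 < 1:
        raise ValueError(f"n0 must be >= 1, got {n0}")
    return 1.0 / (params.mu * math.sqrt(n0))
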