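"""Temporal variation from zero-truncated-Poisson inocula with deterministic growth.

Pipetting a fixed volume of a dilute culture delivers a Poisson number of
cells per well.  Conditioning on at least one cell (only growing wells are
observed) gives a zero-truncated Poisson inoculum M.  If growth is then
deterministic and exponential, n(t) = M * exp(mu*t), the threshold-crossing
time is T(M) = ln(omega/M)/mu and all temporal variation comes from the
inoculum draw.  The TSD of T(M) is exactly (1/mu) * SD(ln M) under the
zero-truncated law — independent of the threshold — and for large shape
parameter the delta method reduces it to 1/(mu*sqrt(n0)), the same
inverse-square-root law as the simple birth process.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import special

from .sbp_exact import GrowthParams

__all__ = [
    "TruncatedPoissonInoculum",
    "DeltaMoments",
    "zt_pmf",
    "zt_mean",
    "deterministic_fpt",
    "tsd_zt_exact",
    "delta_moments",
]


@dataclass(frozen=True)
class TruncatedPoissonInoculum:
    """Zero-truncated Poisson inoculum with shape parameter ``shape`` (> 0).

    The mean inoculum size is ``shape / (1 - exp(-shape))``, which exceeds
    both 1 and the shape parameter.
    """

    shape: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be positive, got {self.shape}")


class DeltaMoments(NamedTuple):
    mean_approx: float  # hours
    var_approx: float  # hours^2
    tsd_approx: float  # hours
    mean_correction: float  # the 1/(2 mu n0) term, exposed separately


def zt_pmf(inoc: TruncatedPoissonInoculum, k):
    """P(M = k) for the zero-truncated Poisson: Poisson pmf renormalized over k >= 1."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer) and np.any(
        k_arr != np.floor(k_arr)
    ):
        raise ValueError("k must be a non-negative integer")
    scalar = k_arr.ndim == 0
    k_arr = np.atleast_1d(k_arr).astype(np.int64)
    if np.any(k_arr < 0):
        raise ValueError("k must be >= 0")
    lam = inoc.shape
    norm = -np.expm1(-lam)  # 1 - e^{-lam}
    out = np.zeros(k_arr.shape, dtype=float)
    pos = k_arr >= 1
    kv = k_arr[pos].astype(float)
    out[pos] = np.exp(kv * math.log(lam) - lam - special.gammaln(kv + 1)) / norm
    return float(out[0]) if scalar else out


def zt_mean(inoc: TruncatedPoissonInoculum) -> float:
    """Mean of the zero-truncated Poisson: ``shape / (1 - exp(-shape))``."""
    return inoc.shape / -math.expm1(-inoc.shape)


def deterministic_fpt(params: GrowthParams, omega: float, m: float) -> float:
    """Crossing time (1/mu) * ln(omega/m) of deterministic exponential growth.

    ``m`` is the (possibly non-integer) starting abundance, 0 < m < omega.
    """
    if not (0 < m < omega):
        raise ValueError(f"need 0 < m < omega, got m={m}, omega={omega}")
    return math.log(omega / m) / params.mu


def tsd_zt_exact(
    params: GrowthParams, inoc: TruncatedPoissonInoculum, rtol: float = 1e-15
) -> float:
    """Exact TSD of T(M) = ln(omega/M)/mu with zero-truncated-Poisson M.

    Equals (1/mu) * sqrt(Var[ln M]) under the zero-truncated law; the
    threshold omega cancels.  The series over k is truncated well past the
    Poisson mode and the remainder is verified to be negligible.
    """
    lam = inoc.shape
    k_max = int(lam + 12.0 * math.sqrt(lam) + 60.0)
    ks = np.arange(1, k_max + 1, dtype=float)
    log_w = ks * math.log(lam) - lam - special.gammaln(ks + 1)
    w = np.exp(log_w) / -math.expm1(-lam)
    total = w.sum()
    # tail guard: normalization must be complete to ~machine precision
    if not (abs(total - 1.0) < max(rtol * 1e2, 1e-12)):
        raise RuntimeError(
            f"zero-truncated Poisson series did not converge (mass={total!r})"
        )
    log_k = np.log(ks)
    m1 = float(np.dot(w, log_k))
    m2 = float(np.dot(w, log_k**2))
    var_log = max(m2 - m1 * m1, 0.0)
    return math.sqrt(var_log) / params.mu


def delta_moments(
    params: GrowthParams, omega: float, inoc: TruncatedPoissonInoculum
) -> DeltaMoments:
    """Delta-method FPT moments for Poisson inocula + deterministic growth.

    For large shape n0 (Poisson ~ Normal(n0, n0)):

    * mean ~= ln(omega/n0)/mu + 1/(2 mu n0)
    * variance ~= 1/(mu^2 n0)
    * TSD ~= 1/(mu sqrt(n0))

    The second-order mean correction is returned separately.  Accuracy is
    O(1/n0^2); a warning is emitted below shape = 5 where the expansion is
    crude.
    """
    n0 = inoc.shape
    if omega <= n0:
        raise ValueError(f"omega must exceed the shape parameter, got {omega} <= {n0}")
    if n0 < 5:
        warnings.warn(
            f"delta-method moments are inaccurate for shape={n0} < 5",
            stacklevel=2,
        )
    mu = params.mu
    correction = 1.0 / (2.0 * mu * n0)
    mean = math.log(omega / n0) / mu + correction
    var = 1.0 / (mu**2 * n0)
    return DeltaMoments(
        mean_approx=mean,
        var_approx=var,
        tsd_approx=1.0 / (mu * math.sqrt(n0)),
        mean_correction=correction,
    )
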