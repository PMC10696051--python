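"""Stochastic simulators for exponentially growing populations.

Covers every combination of inoculation (exact count or zero-truncated
Poisson) and growth dynamics used in the temporal-variation analysis:

* the simple birth process (SBP), sampled exactly as a sum of independent
  exponential waiting times Exp(mu*n) for n = inoculum .. omega-1 — no
  event-by-event simulation needed for first-passage times;
* age-structured (Bellman–Harris) growth, where each individual lives an
  i.i.d. division time drawn from an Erlang law (a k-stage process whose
  division-time distribution is a rescaled chi-squared with 2k degrees of
  freedom; coefficient of variation 1/sqrt(k)), simulated with an event
  queue;
* deterministic exponential growth;
* the two-step model (SBP until a switch time, deterministic afterwards)
  used to quantify how temporal variance accumulates at early times.

Division-time laws are parameterized in minutes (lab convention);
first-passage times are always returned in hours.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .sbp_exact import GrowthParams

__all__ = [
    "DivisionTimeLaw",
    "InoculumLaw",
    "FptSample",
    "ModelSpec",
    "TrajectorySet",
    "sample_sbp_fpt",
    "sample_age_structured_fpt",
    "sample_trajectories",
    "two_step_variance",
    "sample_two_step_fpt",
]

MINUTES_PER_HOUR = 60.0


@dataclass(frozen=True)
class DivisionTimeLaw:
    """Distribution of an individual's division time.

    ``stage-structured`` is a k-stage Erlang: progression through k
    sequential Poisson stages, i.e. Gamma(k, mean/k), equivalently a
    chi-squared with 2k degrees of freedom rescaled to the requested mean.
    Its coefficient of variation is 1/sqrt(k); k=20 gives the ~22% CV
    typical of bacteria.  ``exponential`` is the k=1 special case (CV 100%),
    which makes age-structured growth coincide with the simple birth
    process.

    Parameters
    ----------
    family : {"exponential", "stage-structured"}
    mean_division_time : float
        Mean division time in minutes (> 0).
    stages : int
        Number of Erlang stages k >= 1; must be 1 for the exponential family.
    """

    family: Literal["exponential", "stage-structured"]
    mean_division_time: float
    stages: int = 1

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "stage-structured"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (np.isfinite(self.mean_division_time) and self.mean_division_time > 0):
            raise ValueError("mean_division_time must be positive (minutes)")
        if int(self.stages) != self.stages or self.stages < 1:
            raise ValueError("stages must be an integer >= 1")
        if self.family == "exponential" and self.stages != 1:
            raise ValueError("exponential family requires stages == 1")

    @property
    def cv(self) -> float:
        """Coefficient of variation of the division time: 1/sqrt(stages)."""
        return 1.0 / math.sqrt(self.stages)

    def matched_rate(self) -> float:
        """Rate mu (per hour) such that ln(2)/mu equals the mean division time."""
        return math.log(2.0) / (self.mean_division_time / MINUTES_PER_HOUR)

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        """Draw division times in minutes."""
        k = self.stages
        return rng.gamma(shape=k, scale=self.mean_division_time / k, size=size)


@dataclass(frozen=True)
class InoculumLaw:
    """Inoculation model: an exact count or a zero-truncated Poisson draw.

    ``value`` is the exact count (integer >= 1) or the Poisson shape
    parameter (> 0).
    """

    kind: Literal["exact", "zero-truncated-poisson"]
    value: float

    def __post_init__(self) -> None:
        if self.kind == "exact":
            if int(self.value) != self.value or self.value < 1:
                raise ValueError("exact inoculum must be an integer >= 1")
        elif self.kind == "zero-truncated-poisson":
            if not self.value > 0:
                raise ValueError("Poisson shape must be > 0")
        else:
            raise ValueError(f"unknown inoculum kind {self.kind!r}")

    def mean(self) -> float:
        """Mean inoculum size (the zero-truncated mean for Poisson inocula)."""
        if self.kind == "exact":
            return float(self.value)
        return self.value / -math.expm1(-self.value)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw inoculum sizes; zero-truncated sampling uses the inverse CDF."""
        if self.kind == "exact":
            return np.full(size, int(self.value), dtype=np.int64)
        lam = self.value
        p0 = math.exp(-lam)
        u = p0 + rng.random(size) * (1.0 - p0)
        k = stats.poisson.ppf(u, lam).astype(np.int64)
        return np.maximum(k, 1)


@dataclass
class FptSample:
    """Replicate first-passage times at a threshold, with provenance."""

    model: str
    threshold: int
    times: np.ndarray  # hours
    seed: int | None
    n_reps: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0):
            raise ValueError("first-passage times must be non-negative")
        if len(self.times) != self.n_reps:
            raise ValueError("length of times must equal n_reps")


@dataclass(frozen=True)
class ModelSpec:
    """A growth/inoculum combination for trajectory sampling.

    ``growth`` selects the dynamics; ``mu`` (per hour) applies to the
    ``sbp`` and ``deterministic`` kinds, ``law`` to ``age-structured``.
    """

    growth: Literal["sbp", "deterministic", "age-structured"]
    inoculum: InoculumLaw
    mu: float | None = None
    law: DivisionTimeLaw | None = None

    def __post_init__(self) -> None:
        if self.growth in ("sbp", "deterministic"):
            if self.mu is None or not self.mu > 0:
                raise ValueError(f"{self.growth} model requires mu > 0")
        elif self.growth == "age-structured":
            if self.law is None:
                raise ValueError("age-structured model requires a DivisionTimeLaw")
        else:
            raise ValueError(f"unknown growth kind {self.growth!r}")


@dataclass
class TrajectorySet:
    """Abundance-versus-time paths on a shared regular grid."""

    times: np.ndarray  # hours
    values: np.ndarray  # (n_reps, n_times)
    model: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.times):
            raise ValueError("values must have one column per time point")


def sample_sbp_fpt(
    params: GrowthParams,
    inoc: InoculumLaw,
    omega: int,
    n_reps: int,
    seed: int,
) -> FptSample:
    """Exact first-passage-time sampling for the simple birth process.

    Each replicate draws an inoculum k, then the FPT is the sum of
    independent waiting times Exp(mu*n) for n = k .. omega-1 (Markov
    property) — no event loop.  Replicates whose inoculum already meets the
    threshold get FPT 0 (with a warning).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if omega <= inoc.mean():
        raise ValueError(
            f"threshold omega={omega} does not exceed the mean inoculum "
            f"{inoc.mean():.3g}"
        )
    rng = np.random.default_rng(seed)
    k = inoc.sample(rng, n_reps)
    if np.any(k >= omega):
        warnings.warn(
            "some inocula meet or exceed the threshold; their FPT is 0",
            stacklevel=2,
        )
    times = np.empty(n_reps, dtype=float)
    rates = params.mu * np.arange(1, omega, dtype=float)  # rate for n=1..omega-1
    # chunk replicates so the (reps x omega-1) exponential block stays small
    chunk = max(1, int(2e7 // max(omega - 1, 1)))
    for lo in range(0, n_reps, chunk):
        hi = min(lo + chunk, n_reps)
        e = rng.exponential(size=(hi - lo, omega - 1)) / rates
        # suffix sums: s[:, j] = sum over waiting times for n >= j+1
        s = np.hstack(
            [np.cumsum(e[:, ::-1], axis=1)[:, ::-1], np.zeros((hi - lo, 1))]
        )
        kk = np.minimum(k[lo:hi], omega)
        times[lo:hi] = s[np.arange(hi - lo), kk - 1]
    return FptSample(
        model=f"sbp/{inoc.kind}", threshold=omega, times=times, seed=seed,
        n_reps=n_reps,
    )


def _age_structured_single_fpt(
    law: DivisionTimeLaw,
    k: int,
    omega: int,
    rng: np.random.Generator,
    initial_phase: str,
) -> float:
    """One Bellman–Harris replicate; returns the FPT in minutes."""
    mean = law.mean_division_time
    if initial_phase == "uniform":
        # individuals sit at a random point of their cycle; the first
        # division lands uniformly within one doubling window ln2/mu_eff,
        # which equals the mean division time for the matched rate
        init = rng.random(k) * mean
    elif initial_phase == "exponential":
        init = rng.exponential(mean, k)
    elif initial_phase == "zero":
        init = law.draw(rng, k)
    else:
        raise ValueError(f"unknown initial_phase {initial_phase!r}")
    if k >= omega:
        return 0.0
    heap = list(init)
    heapq.heapify(heap)
    n_div = omega - k
    draws = law.draw(rng, 2 * n_div)
    push = heapq.heappush
    pop = heapq.heappop
    t = 0.0
    idx = 0
    for _ in range(n_div):
        t = pop(heap)
        push(heap, t + draws[idx])
        push(heap, t + draws[idx + 1])
        idx += 2
    return t


def sample_age_structured_fpt(
    law: DivisionTimeLaw,
    inoc: InoculumLaw,
    omega: int,
    n_reps: int,
    seed: int,
    initial_phase: Literal["uniform", "exponential", "zero"] = "uniform",
) -> FptSample:
    """Event-queue Bellman–Harris simulation of first-passage times.

    Each division replaces one individual by two with fresh division-time
    draws; the FPT is recorded at the division event when the population
    count first reaches ``omega``.  ``initial_phase`` controls the first
    division of inoculated individuals: ``uniform`` draws it uniformly on
    one mean-division-time window (individuals at a random point of their
    cycle, the default), ``exponential`` draws it from an exponential with
    the same mean (memoryless start), ``zero`` gives everyone a fresh full
    cycle.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if omega < inoc.mean():
        raise ValueError("threshold below the mean inoculum")
    rng = np.random.default_rng(seed)
    ks = inoc.sample(rng, n_reps)
    times_min = np.empty(n_reps, dtype=float)
    for i in range(n_reps):
        times_min[i] = _age_structured_single_fpt(
            law, int(ks[i]), omega, rng, initial_phase
        )
    return FptSample(
        model=f"age-structured(k={law.stages})/{inoc.kind}",
        threshold=omega,
        times=times_min / MINUTES_PER_HOUR,
        seed=seed,
        n_reps=n_reps,
    )


def _sbp_event_times(
    rng: np.random.Generator, mu: float, k: int, horizon: float, max_events: int
) -> np.ndarray:
    """Division-event times (hours) of one SBP path up to ``horizon``."""
    out = []
    t = 0.0
    n = k
    while len(out) < max_events:
        t += rng.exponential(1.0 / (mu * n))
        if t > horizon:
            break
        out.append(t)
        n += 1
    else:
        warnings.warn("SBP trajectory hit the event budget", stacklevel=3)
    return np.asarray(out)


def sample_trajectories(
    model: ModelSpec,
    horizon: float,
    grid_step: float,
    n_reps: int,
    seed: int,
    max_events: int = 1_000_000,
) -> TrajectorySet:
    """Abundance paths on a regular grid (piecewise-constant between events).

    ``horizon`` in hours, ``grid_step`` in minutes.  Stochastic paths are
    sampled at event level, so keep ``horizon`` small enough that the
    expected final abundance stays within the event budget.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    grid = np.arange(0.0, horizon + 1e-12, grid_step / MINUTES_PER_HOUR)
    if len(grid) == 0:
        raise ValueError("empty time grid")
    rng = np.random.default_rng(seed)
    ks = model.inoculum.sample(rng, n_reps)
    values = np.empty((n_reps, len(grid)), dtype=float)
    if model.growth == "deterministic":
        values[:] = ks[:, None] * np.exp(model.mu * grid[None, :])
    elif model.growth == "sbp":
        for i in range(n_reps):
            ev = _sbp_event_times(rng, model.mu, int(ks[i]), horizon, max_events)
            values[i] = ks[i] + np.searchsorted(ev, grid, side="right")
    else:  # age-structured
        law = model.law
        for i in range(n_reps):
            k = int(ks[i])
            init = rng.random(k) * law.mean_division_time
            heap = list(init)
            heapq.heapify(heap)
            ev = []
            horizon_min = horizon * MINUTES_PER_HOUR
            while len(ev) < max_events:
                t = heapq.heappop(heap)
                if t > horizon_min:
                    break
                ev.append(t)
                d = law.draw(rng, 2)
                heapq.heappush(heap, t + d[0])
                heapq.heappush(heap, t + d[1])
            ev = np.asarray(ev) / MINUTES_PER_HOUR
            values[i] = k + np.searchsorted(ev, grid, side="right")
    return TrajectorySet(times=grid, values=values, model=model.growth)


def two_step_variance(params: GrowthParams, n0: int, t_switch: float) -> float:
    """Leading-order temporal variance of the two-step growth model.

    SBP growth until ``t_switch`` (hours), deterministic afterwards:
    ``Var(T) ~= (1 - e^{-mu t}) / (mu^2 n0)``.  Reaches half its asymptote
    after a single doubling time ln(2)/mu and saturates at 1/(mu^2 n0) —
    temporal variance accumulates while populations are still small.
    """
    if t_switch < 0:
        raise ValueError("t_switch must be non-negative")
    mu = params.mu
    return -math.expm1(-mu * t_switch) / (mu**2 * n0)


def sample_two_step_fpt(
    params: GrowthParams,
    n0: int,
    t_switch: float,
    omega: float,
    n_reps: int,
    seed: int,
) -> FptSample:
    """Sample FPTs of the two-step model (SBP to ``t_switch``, then deterministic).

    N(t_switch) is a sum of n0 i.i.d. geometric variables (the SBP abundance
    law per founding lineage); the FPT is then ln(omega/N)/mu.  The
    threshold should greatly exceed typical N(t_switch); a warning is
    emitted otherwise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mu = params.mu
    expected_n = n0 * math.exp(mu * t_switch)
    if omega < 10 * expected_n:
        warnings.warn(
            "threshold is not much larger than the expected switch abundance; "
            "the deterministic approximation may be poor",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    p = math.exp(-mu * t_switch)
    n_switch = rng.geometric(p, size=(n_reps, n0)).sum(axis=1)
    times = np.log(omega / n_switch) / mu
    return FptSample(
        model="two-step", threshold=int(omega), times=times, seed=seed,
        n_reps=n_reps,
    )
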