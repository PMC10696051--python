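"""Synthetic plate-reader datasets with known ground truth.

Generates OD600 well x time matrices with the statistical structure the
plate pipeline assumes: Poisson (or exact) inocula, stochastic early
growth, smooth saturation toward a carrying capacity, a per-plate constant
measurement background, and additive Gaussian read noise at plate-reader
resolution.  Also generates spot-plating colony-count tables (untruncated
Poisson — plates can show zero colonies) for inoculum-size inference.

Stochastic growth is simulated at event level only while populations are
small — where essentially all temporal variance is generated, since
contributions fall off as the inverse square of the population size — and
continued deterministically at the model's asymptotic (Malthusian) rate
from a switch abundance onward.  That makes OD-scale thresholds (millions
of cells) reachable while preserving the crossing-time statistics of the
full stochastic model.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .desync import renewal_poles
from .plate_pipeline import PlateRun
from .simulate import (
    MINUTES_PER_HOUR,
    DivisionTimeLaw,
    InoculumLaw,
    _sbp_event_times,
)

__all__ = ["FixtureConfig", "generate_plate", "generate_spot_counts"]

# standard-curve anchor: OD 0.03 corresponds to 1.4e7 CFU
DEFAULT_OD_PER_CFU = 0.03 / 1.4e7


@dataclass(frozen=True)
class FixtureConfig:
    """Recipe for one synthetic plate.

    Defaults mirror a typical bench setup: 42 replicate wells plus 6
    blanks, reads every 2 min, a baseline within the 0.099–0.121 range
    observed on real plates, additive read noise at the 0.001 OD
    instrument resolution, and a linear OD-CFU map anchored at
    OD 0.03 = 1.4e7 CFU.
    """

    growth_model: Literal["sbp", "deterministic", "age-structured"] = "sbp"
    mu: float = 1.8  # per hour (sbp / deterministic)
    division_law: DivisionTimeLaw | None = None  # age-structured
    inoculum_kind: Literal["exact", "poisson"] = "poisson"
    inoculum_value: float = 2.8
    carrying_capacity_cfu: float = 2.0e8
    od_per_cfu: float = DEFAULT_OD_PER_CFU
    baseline: float = 0.110
    noise_sd: float = 0.001
    read_interval: float = 2.0  # minutes
    horizon: float = 12.0  # hours
    wells_per_group: int = 42
    n_blanks: int = 6
    switch_abundance: int = 1000
    lag_minutes: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_per_cfu <= 0 or self.baseline < 0 or self.read_interval <= 0:
            raise ValueError("invalid optics/grid configuration")
        if self.growth_model == "age-structured" and self.division_law is None:
            raise ValueError("age-structured fixtures need a division_law")

    def effective_rate(self) -> float:
        """Asymptotic exponential rate (per hour) of the configured model."""
        if self.growth_model == "age-structured":
            return renewal_poles(self.division_law).malthusian_rate * MINUTES_PER_HOUR
        return self.mu


def _saturate(n: np.ndarray, capacity: float) -> np.ndarray:
    """Cap exponential growth smoothly: identity below 40% of capacity,
    then exponential approach to the capacity (C1-continuous)."""
    c = 0.4 * capacity
    out = np.asarray(n, dtype=float).copy()
    high = out > c
    out[high] = capacity - (capacity - c) * np.exp(-(out[high] - c) / (capacity - c))
    return out


def _stochastic_log_abundance(
    cfg: FixtureConfig, k: int, t_hours: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """ln(abundance) on the grid for one well, before saturation/optics."""
    mu = cfg.effective_rate()
    if cfg.growth_model == "deterministic" or k >= cfg.switch_abundance:
        return math.log(k) + mu * t_hours
    if cfg.growth_model == "sbp":
        # exact event times up to the switch abundance, deterministic after
        ev = []
        t = 0.0
        n = k
        while n < cfg.switch_abundance:
            t += rng.exponential(1.0 / (cfg.mu * n))
            ev.append(t)
            n += 1
        ev = np.asarray(ev)
    else:  # age-structured: event-queue until the switch abundance
        import heapq

        law = cfg.division_law
        heap = list(rng.random(k) * law.mean_division_time)
        heapq.heapify(heap)
        n_div = cfg.switch_abundance - k
        draws = law.draw(rng, 2 * n_div)
        ev_min = np.empty(n_div)
        for i in range(n_div):
            t = heapq.heappop(heap)
            ev_min[i] = t
            heapq.heappush(heap, t + draws[2 * i])
            heapq.heappush(heap, t + draws[2 * i + 1])
        ev = ev_min / MINUTES_PER_HOUR
    t_switch = ev[-1]
    counts = k + np.searchsorted(ev, t_hours, side="right")
    log_n = np.log(counts.astype(float))
    after = t_hours > t_switch
    log_n[after] = math.log(cfg.switch_abundance) + mu * (t_hours[after] - t_switch)
    return log_n


def generate_plate(cfg: FixtureConfig) -> tuple[PlateRun, dict]:
    """Generate one synthetic plate and its ground-truth record.

    Returns the :class:`PlateRun` (raw OD only; background subtraction and
    QC are the pipeline's job) and a dictionary with the true growth rate,
    the per-well inocula, the optics constants, and the noiseless OD matrix
    from which exact crossing times can be computed.
    """
    rng = np.random.default_rng(cfg.seed)
    t_min = np.arange(0.0, cfg.horizon * MINUTES_PER_HOUR + 1e-9, cfg.read_interval)
    t_hours = t_min / MINUTES_PER_HOUR
    lag_h = cfg.lag_minutes / MINUTES_PER_HOUR
    t_growth = np.clip(t_hours - lag_h, 0.0, None)

    wells, inocula, clean_cols = [], [], []
    for i in range(cfg.wells_per_group):
        well = f"W{i + 1:02d}"
        if cfg.inoculum_kind == "exact":
            k = int(cfg.inoculum_value)
        else:
            k = int(rng.poisson(cfg.inoculum_value))
        wells.append(well)
        inocula.append(k)
        if k == 0:
            clean_cols.append(np.zeros_like(t_hours))
            continue
        log_n = _stochastic_log_abundance(cfg, k, t_growth, rng)
        n = _saturate(np.exp(log_n), cfg.carrying_capacity_cfu)
        clean_cols.append(cfg.od_per_cfu * n)
    blank_wells = [f"B{i + 1:02d}" for i in range(cfg.n_blanks)]
    for _ in blank_wells:
        clean_cols.append(np.zeros_like(t_hours))

    clean = np.column_stack(clean_cols)
    noise = rng.normal(0.0, cfg.noise_sd, size=clean.shape) if cfg.noise_sd else 0.0
    od_raw = pd.DataFrame(
        clean + cfg.baseline + noise,
        index=pd.Index(t_min, name="time_min"),
        columns=wells + blank_wells,
    )
    meta = pd.DataFrame(
        {
            "well": wells + blank_wells,
            "group": [f"inoc_{cfg.inoculum_value:g}"] * len(wells)
            + ["blank"] * len(blank_wells),
            "role": ["sample"] * len(wells) + ["blank"] * len(blank_wells),
        }
    ).set_index("well")
    run = PlateRun(od_raw=od_raw, meta=meta, plate_id=f"synthetic-{cfg.seed}")
    truth = {
        "config": {
            **{
                k: v
                for k, v in asdict(cfg).items()
                if k != "division_law"
            },
            "division_law": asdict(cfg.division_law) if cfg.division_law else None,
        },
        "true_rate_per_hour": cfg.effective_rate(),
        "inocula": dict(zip(wells, inocula)),
        "n_zero_inocula": int(sum(k == 0 for k in inocula)),
        "noiseless_od": pd.DataFrame(
            clean + cfg.baseline,
            index=od_raw.index,
            columns=od_raw.columns,
        ),
    }
    return run, truth


def true_crossing_times(truth: dict, od_threshold: float) -> dict[str, float]:
    """Exact crossing times (hours) of the noiseless, background-free OD."""
    clean = truth["noiseless_od"]
    baseline = truth["config"]["baseline"]
    t_min = clean.index.to_numpy(dtype=float)
    out = {}
    for well in clean.columns:
        y = clean[well].to_numpy(dtype=float) - baseline
        above = y >= od_threshold
        if not above.any():
            continue
        j = int(above.argmax())
        if j == 0:
            out[well] = 0.0
            continue
        frac = (od_threshold - y[j - 1]) / (y[j] - y[j - 1])
        out[well] = (t_min[j - 1] + frac * (t_min[j] - t_min[j - 1])) / MINUTES_PER_HOUR
    return out


def generate_spot_counts(shape: float, n_spots: int, seed: int) -> dict:
    """Spot-plating colony counts: i.i.d. Poisson(shape), zeros included.

    The summary reports the zero fraction and the mean of the nonzero
    counts (the empirical zero-truncated mean used as the inoculum-size
    estimate for growing wells).
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if shape < 0:
        raise ValueError("shape must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(shape, n_spots)
    nonzero = counts[counts > 0]
    return {
        "counts": counts,
        "shape": shape,
        "n_spots": n_spots,
        "zero_fraction": float((counts == 0).mean()),
        "zt_mean": float(nonzero.mean()) if len(nonzero) else math.nan,
        "mean": float(counts.mean()),
    }
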