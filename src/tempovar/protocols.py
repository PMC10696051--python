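"""Canonical simulation protocols for comparing growth/inoculation models.

The reference comparison runs every combination of inoculation (exact or
zero-truncated Poisson) and growth dynamics (simple birth process,
deterministic exponential, age-structured) over a grid of inoculum sizes at
a fixed threshold, and examines how the TSD scales with the (zero-truncated
mean) inoculum size.  All five model combinations follow the same
inverse-square-root power law.  Defaults: threshold 500 individuals, growth
rate 1.66/hour (25-minute division time), 20-stage division law, 2000
replicates per point.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .poisson_inocula import TruncatedPoissonInoculum, tsd_zt_exact, zt_mean
from .sbp_exact import GrowthParams, PassageProblem, fpt_moments
from .simulate import (
    DivisionTimeLaw,
    InoculumLaw,
    sample_age_structured_fpt,
    sample_sbp_fpt,
)

__all__ = ["FIVE_MODELS", "five_model_tsd_table", "power_law_slope"]

FIVE_MODELS = (
    "sbp-exact",
    "deterministic-poisson",
    "sbp-poisson",
    "age-exact",
    "age-poisson",
)


def five_model_tsd_table(
    n0_grid=tuple(range(1, 31)),
    omega: int = 500,
    mu: float = 1.66,
    law: DivisionTimeLaw | None = None,
    n_reps: int = 2000,
    seed: int = 0,
    models=FIVE_MODELS,
) -> pd.DataFrame:
    """TSD versus inoculum size for the five model combinations.

    Exactly solvable models (SBP with exact inocula; deterministic growth
    with Poisson inocula) are evaluated in closed form; the rest are
    simulated with ``n_reps`` replicates each.  The returned frame has one
    row per (model, inoculum) with the zero-truncated mean inoculum size as
    the abscissa for Poisson models.
    """
    params = GrowthParams(mu)
    if law is None:
        law = DivisionTimeLaw("stage-structured", 25.0, 20)
    rows = []
    rng = np.random.default_rng(seed)
    for model in models:
        for n0 in n0_grid:
            if model == "sbp-exact":
                tsd = fpt_moments(params, PassageProblem(n0, omega)).tsd
                x = float(n0)
            elif model == "deterministic-poisson":
                inoc = TruncatedPoissonInoculum(float(n0))
                tsd = tsd_zt_exact(params, inoc)
                x = zt_mean(inoc)
            elif model == "sbp-poisson":
                sub_seed = int(rng.integers(2**31))
                s = sample_sbp_fpt(
                    params, InoculumLaw("zero-truncated-poisson", float(n0)),
                    omega, n_reps, sub_seed,
                )
                tsd = float(np.std(s.times, ddof=1))
                x = zt_mean(TruncatedPoissonInoculum(float(n0)))
            elif model == "age-exact":
                sub_seed = int(rng.integers(2**31))
                s = sample_age_structured_fpt(
                    law, InoculumLaw("exact", n0), omega, n_reps, sub_seed
                )
                tsd = float(np.std(s.times, ddof=1))
                x = float(n0)
            elif model == "age-poisson":
                sub_seed = int(rng.integers(2**31))
                s = sample_age_structured_fpt(
                    law, InoculumLaw("zero-truncated-poisson", float(n0)),
                    omega, n_reps, sub_seed,
                )
                tsd = float(np.std(s.times, ddof=1))
                x = zt_mean(TruncatedPoissonInoculum(float(n0)))
            else:
                raise ValueError(f"unknown model {model!r}")
            rows.append(
                dict(model=model, n0=n0, mean_inoculum=x, tsd_hours=tsd)
            )
    return pd.DataFrame(rows)


def power_law_slope(table: pd.DataFrame, model: str) -> float:
    """OLS slope of log TSD versus log mean inoculum size for one model."""
    sub = table[table["model"] == model]
    fit = stats.linregress(
        np.log(sub["mean_inoculum"]), np.log(sub["tsd_hours"])
    )
    return float(fit.slope)
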