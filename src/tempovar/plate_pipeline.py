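"""Plate-reader OD600 growth-curve processing.

Takes a 96-well-plate style optical-density time series (one column per
well, readings every 2–3 minutes), removes the per-plate measurement
background, applies quality-control filters, extracts log-phase growth
rates from a sliding window around a threshold OD, computes temporal
standard deviations of threshold-crossing times as a function of the OD
threshold, and checks for a lag phase by comparing observed crossing times
with the no-lag deterministic prediction through an OD-to-CFU standard
curve.

Within the plate reader's sensitivity range OD600 is proportional to cell
density (Beer–Lambert), so OD thresholds stand in for abundance thresholds.
Plate times are in minutes; crossing times and rates are reported in hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import TsdEstimate, threshold_crossing_times, tsd_with_ci
from .simulate import MINUTES_PER_HOUR, FptSample, TrajectorySet

__all__ = [
    "PlateRun",
    "StandardCurve",
    "load_plate",
    "subtract_background",
    "apply_qc_filters",
    "log_window_growth_rate",
    "tsd_vs_threshold",
    "fit_standard_curve",
    "lag_phase_check",
]

QC_OD_LIMIT_1H = 0.125  # raw OD above this at 1 h flags condensation/misread


@dataclass
class PlateRun:
    """One plate: OD600 well x time matrix plus metadata and QC state.

    ``od_raw`` has the time grid (minutes from inoculation) as its index and
    one column per well.  ``meta`` is indexed by well with at least a
    ``group`` column (inoculum condition) and a ``role`` column
    (``sample``/``blank``).  ``od_corrected`` is populated by
    :func:`subtract_background`; ``qc_flags`` maps flagged wells to omission
    reasons, and flagged wells are excluded from all statistics.
    """

    od_raw: pd.DataFrame
    meta: pd.DataFrame
    od_corrected: pd.DataFrame | None = None
    background: float | None = None
    qc_flags: dict[str, str] = field(default_factory=dict)
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        missing = set(self.od_raw.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"wells missing from metadata: {sorted(missing)}")

    @property
    def times(self) -> np.ndarray:
        """Read times in minutes from inoculation."""
        return self.od_raw.index.to_numpy(dtype=float)

    def good_wells(self, role: str = "sample") -> list[str]:
        return [
            w
            for w in self.od_raw.columns
            if w not in self.qc_flags and self.meta.loc[w, "role"] == role
        ]

    def groups(self) -> list[str]:
        wells = self.good_wells()
        return sorted(self.meta.loc[wells, "group"].unique())


def load_plate(
    od_csv, meta_csv, plate_id: str = "plate", fmt: str = "wide"
) -> PlateRun:
    """Read a plate from tabular text.

    ``wide``: first column is time in minutes, remaining columns are wells.
    ``long``: columns ``time_min``, ``well``, ``od``.  The metadata CSV must
    have columns ``well``, ``group``, ``role``.
    """
    if fmt == "wide":
        od = pd.read_csv(od_csv)
        od = od.set_index(od.columns[0])
        od.index = od.index.astype(float)
    elif fmt == "long":
        long = pd.read_csv(od_csv)
        od = long.pivot(index="time_min", columns="well", values="od")
        od.columns.name = None
    else:
        raise ValueError(f"unknown plate format {fmt!r}")
    meta = pd.read_csv(meta_csv).set_index("well")
    return PlateRun(od_raw=od, meta=meta, plate_id=plate_id)


def subtract_background(run: PlateRun) -> PlateRun:
    """Remove the per-plate measurement background.

    The background is the mean OD across all wells at time zero (light
    occluded by the solution itself) and is subtracted from every reading.
    Recomputing always starts from ``od_raw``, so the operation is
    idempotent.
    """
    t = run.times
    if t[0] != 0:
        raise ValueError("plate has no time-0 readings to estimate background")
    background = float(run.od_raw.iloc[0].mean())
    corrected = run.od_raw - background
    return replace(run, od_corrected=corrected, background=background)


def apply_qc_filters(
    run: PlateRun, manual_exclusions: dict[str, str] | list | None = None
) -> tuple[PlateRun, dict]:
    """Flag wells failing quality control.

    Automatic criterion: raw OD600 above 0.125 at 1 h of growth (initial
    condensation or a measurement error).  ``manual_exclusions`` covers
    conditions that cannot be automated (anaerobic wells, contamination),
    as a well -> reason mapping or a plain list of wells.  Returns the
    flagged run and a report with counts and the omitted fraction.
    """
    t = run.times
    if t[-1] < 60.0:
        raise ValueError("QC requires at least 1 h of data")
    i_1h = int(np.argmin(np.abs(t - 60.0)))
    flags = dict(run.qc_flags)
    for well in run.od_raw.columns:
        if run.meta.loc[well, "role"] != "sample":
            continue
        if run.od_raw[well].iloc[i_1h] > QC_OD_LIMIT_1H:
            flags[well] = f"raw OD > {QC_OD_LIMIT_1H} at 1 h"
    if manual_exclusions:
        if isinstance(manual_exclusions, dict):
            flags.update(manual_exclusions)
        else:
            flags.update({w: "manual exclusion" for w in manual_exclusions})
    n_samples = int((run.meta["role"] == "sample").sum())
    report = {
        "n_wells": n_samples,
        "n_flagged": len(flags),
        "fraction_omitted": len(flags) / n_samples if n_samples else 0.0,
        "flags": flags,
    }
    return replace(run, qc_flags=flags), report


def _crossing_time_minutes(
    t: np.ndarray, y: np.ndarray, threshold: float
) -> float | None:
    """Interpolated first crossing of ``threshold`` by signal ``y``; None if never."""
    above = y >= threshold
    if not above.any():
        return None
    j = int(above.argmax())
    if j == 0:
        return float(t[0])
    if y[j] > y[j - 1]:
        frac = (threshold - y[j - 1]) / (y[j] - y[j - 1])
    else:
        frac = 1.0
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def log_window_growth_rate(
    run: PlateRun, od_threshold: float = 0.03, window: float = 30.0
) -> dict:
    """Log-phase growth rate from a window centred on the threshold crossing.

    For each retained sample well, locates the time ``t0`` at which the
    background-corrected OD first reaches ``od_threshold`` and fits an
    ordinary least-squares line to ln(OD) over the ``window``-minute window
    centred on ``t0``.  The pooled rate is the unweighted mean of per-well
    slopes across replicates and inoculum groups, in 1/hour.  Wells never
    reaching the threshold are skipped (and listed); a window extending
    before the first sample raises.
    """
    if run.od_corrected is None:
        raise ValueError("run must be background-subtracted first")
    t = run.times
    half = window / 2.0
    per_well: dict[str, float] = {}
    skipped: list[str] = []
    for well in run.good_wells():
        y = run.od_corrected[well].to_numpy(dtype=float)
        t0 = _crossing_time_minutes(t, y, od_threshold)
        if t0 is None:
            skipped.append(well)
            continue
        if t0 - half < t[0]:
            raise ValueError(
                f"well {well}: the {window:g}-min window around its "
                f"threshold crossing extends before the first sample"
            )
        sel = (t >= t0 - half) & (t <= t0 + half)
        ts = t[sel] / MINUTES_PER_HOUR
        ys = y[sel]
        ok = ys > 0  # non-positive corrected ODs are masked, never clipped
        if ok.sum() < 2:
            skipped.append(well)
            continue
        fit = stats.linregress(ts[ok], np.log(ys[ok]))
        per_well[well] = float(fit.slope)
    if not per_well:
        raise ValueError("no well yielded a growth rate")
    pooled = float(np.mean(list(per_well.values())))
    by_group: dict[str, float] = {}
    for g in run.groups():
        wells = [
            w for w in per_well if run.meta.loc[w, "group"] == g
        ]
        if wells:
            by_group[g] = float(np.mean([per_well[w] for w in wells]))
    return {
        "per_well": per_well,
        "pooled_rate": pooled,
        "by_group": by_group,
        "skipped_wells": skipped,
        "od_threshold": od_threshold,
        "window_min": window,
    }


def tsd_vs_threshold(
    run: PlateRun,
    thresholds=None,
    level: float = 0.68,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """TSD of crossing times per inoculum group, across an OD-threshold grid.

    Default grid: 8 log-spaced thresholds over OD 0.01–0.3.  Groups with
    fewer than two crossing wells at a threshold are omitted with a
    warning.  TSDs are in hours.
    """
    if run.od_corrected is None:
        raise ValueError("run must be background-subtracted first")
    if thresholds is None:
        thresholds = np.geomspace(0.01, 0.3, 8)
    t_hours = run.times / MINUTES_PER_HOUR
    rows = []
    for g in run.groups():
        wells = [w for w in run.good_wells() if run.meta.loc[w, "group"] == g]
        values = run.od_corrected[wells].to_numpy(dtype=float).T
        traj = TrajectorySet(times=t_hours, values=values, model=f"plate:{g}")
        for thr in thresholds:
            try:
                sample = threshold_crossing_times(traj, float(thr))
            except ValueError:
                warnings.warn(
                    f"group {g}: no well crosses OD {thr:g}", stacklevel=2
                )
                continue
            if sample.n_reps < 2:
                warnings.warn(
                    f"group {g}: fewer than 2 crossings at OD {thr:g}",
                    stacklevel=2,
                )
                continue
            est = tsd_with_ci(sample, level=level, n_boot=n_boot, seed=seed)
            rows.append(
                dict(
                    group=g,
                    threshold_od=float(thr),
                    tsd_hours=est.tsd,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    n_wells=sample.n_reps,
                    n_excluded=sample.n_excluded,
                )
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StandardCurve:
    """Linear OD600 <-> CFU map, valid over a calibration range of OD."""

    slope: float  # CFU per OD unit
    intercept: float  # CFU
    od_range: tuple[float, float] = (0.01, 0.6)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("standard curve must have positive slope")

    def to_cfu(self, od: float) -> float:
        lo, hi = self.od_range
        if not (lo <= od <= hi):
            warnings.warn(
                f"OD {od:g} outside the calibration range [{lo}, {hi}]",
                stacklevel=2,
            )
        return self.slope * od + self.intercept

    def to_od(self, cfu: float) -> float:
        od = (cfu - self.intercept) / self.slope
        lo, hi = self.od_range
        if not (lo <= od <= hi):
            warnings.warn(
                f"CFU {cfu:g} maps outside the calibration range", stacklevel=2
            )
        return od


def fit_standard_curve(od, cfu) -> StandardCurve:
    """Least-squares linear fit CFU = slope * OD + intercept."""
    od = np.asarray(od, dtype=float)
    cfu = np.asarray(cfu, dtype=float)
    if len(od) < 2:
        raise ValueError("need at least 2 calibration points")
    if np.ptp(od) == 0:
        raise ValueError("degenerate calibration: constant OD")
    fit = stats.linregress(od, cfu)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        od_range=(float(od.min()), float(od.max())),
    )


def lag_phase_check(
    run: PlateRun,
    curve: StandardCurve,
    mu: float,
    n0_by_group: dict[str, float],
    od_threshold: float = 0.03,
) -> pd.DataFrame:
    """Compare no-lag deterministic crossing times with observed means.

    For each inoculum group, the deterministic no-lag model predicts a
    crossing time ``t_det = ln(Omega_CFU / n0) / mu`` where ``Omega_CFU``
    converts the OD threshold through the standard curve.  The report gives
    ``delta = t_det - mean(observed crossing times)`` in hours: a positive
    delta (prediction slower than observation) argues against a
    significant lag phase, since a real lag would make observed times
    exceed the no-lag prediction.
    """
    if run.od_corrected is None:
        raise ValueError("run must be background-subtracted first")
    lo, hi = curve.od_range
    if not (lo <= od_threshold <= hi):
        raise ValueError(
            f"threshold OD {od_threshold} outside calibration range [{lo}, {hi}]"
        )
    omega_cfu = curve.to_cfu(od_threshold)
    t = run.times
    rows = []
    for g, n0 in n0_by_group.items():
        wells = [w for w in run.good_wells() if run.meta.loc[w, "group"] == g]
        obs = []
        for w in wells:
            c = _crossing_time_minutes(
                t, run.od_corrected[w].to_numpy(dtype=float), od_threshold
            )
            if c is not None:
                obs.append(c / MINUTES_PER_HOUR)
        if not obs:
            warnings.warn(f"group {g}: no crossings at OD {od_threshold}",
                          stacklevel=2)
            continue
        t_det = math.log(omega_cfu / n0) / mu
        mean_obs = float(np.mean(obs))
        rows.append(
            dict(
                group=g,
                n0=n0,
                omega_cfu=omega_cfu,
                t_det_hours=t_det,
                mean_observed_hours=mean_obs,
                delta_hours=t_det - mean_obs,
                n_wells=len(obs),
            )
        )
    return pd.DataFrame(rows)
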