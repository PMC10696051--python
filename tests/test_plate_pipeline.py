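"""Plate-reader pipeline: background, QC, rates, TSD tables, lag check."""

import math

import numpy as np
import pandas as pd
import pytest

from tempovar.plate_pipeline import (
    PlateRun,
    StandardCurve,
    apply_qc_filters,
    fit_standard_curve,
    lag_phase_check,
    log_window_growth_rate,
    subtract_background,
    tsd_vs_threshold,
)
from tempovar.synthetic_fixtures import DEFAULT_OD_PER_CFU, FixtureConfig, generate_plate


def _make_run(t_min, od_matrix, wells, groups=None, roles=None):
    groups = groups or ["g1"] * len(wells)
    roles = roles or ["sample"] * len(wells)
    od = pd.DataFrame(od_matrix, index=pd.Index(t_min, name="time_min"), columns=wells)
    meta = pd.DataFrame({"well": wells, "group": groups, "role": roles}).set_index("well")
    return PlateRun(od_raw=od, meta=meta)


@pytest.fixture
def exponential_run():
    """Noiseless plate: OD = 0.005 * e^{1.8 t} + 0.1 baseline, 2-min reads."""
    t_min = np.arange(0, 241, 2.0)
    t_h = t_min / 60.0
    od = 0.1 + 0.005 * np.exp(1.8 * t_h)
    return _make_run(t_min, np.column_stack([od, od]), ["W1", "W2"])


class TestBackground:
    def test_constant_baseline_removed(self, exponential_run):
        run = subtract_background(exponential_run)
        assert run.background == pytest.approx(0.105)
        assert np.allclose(run.od_corrected.iloc[0], 0.0)

    def test_recovers_planted_baseline(self):
        cfg = FixtureConfig(baseline=0.110, noise_sd=0.001, seed=1, wells_per_group=40)
        run, _ = generate_plate(cfg)
        run = subtract_background(run)
        # true OD at t=0 is baseline + od_per_cfu * inoculum (~1e-8, negligible)
        assert run.background == pytest.approx(0.110, abs=3 * 0.001 / math.sqrt(46))

    def test_blank_wells_fluctuate_at_noise_level(self):
        cfg = FixtureConfig(noise_sd=0.001, seed=2)
        run, _ = generate_plate(cfg)
        run = subtract_background(run)
        blanks = run.od_corrected[[w for w in run.od_raw if w.startswith("B")]]
        resid = blanks.to_numpy().ravel()
        # the background estimate carries an offset of ~noise/sqrt(n_wells)
        # that is constant across the whole plate
        n_wells = run.od_raw.shape[1]
        assert abs(resid.mean()) < 3 * 0.001 / math.sqrt(n_wells)
        assert resid.std() == pytest.approx(0.001, rel=0.1)

    def test_idempotent(self, exponential_run):
        once = subtract_background(exponential_run)
        twice = subtract_background(once)
        pd.testing.assert_frame_equal(once.od_corrected, twice.od_corrected)

    def test_requires_time_zero(self):
        run = _make_run(np.array([2.0, 4.0]), np.ones((2, 1)), ["W1"])
        with pytest.raises(ValueError):
            subtract_background(run)


class TestQc:
    def test_boundary_at_1h(self):
        t = np.arange(0, 121, 2.0)
        bad = np.full_like(t, 0.130)
        good = np.full_like(t, 0.120)
        run = _make_run(t, np.column_stack([bad, good]), ["bad", "good"])
        run, report = apply_qc_filters(run)
        assert "bad" in run.qc_flags
        assert "good" not in run.qc_flags
        assert report["n_flagged"] == 1

    def test_planted_bad_wells_fraction(self):
        t = np.arange(0, 121, 2.0)
        n = 84
        od = np.full((len(t), n), 0.110)
        od[:, :3] = 0.140  # three condensation wells
        run = _make_run(t, od, [f"W{i}" for i in range(n)])
        run, report = apply_qc_filters(run)
        assert report["n_flagged"] == 3
        assert report["fraction_omitted"] == pytest.approx(3 / 84)

    def test_manual_exclusions_and_short_run(self):
        t = np.arange(0, 121, 2.0)
        run = _make_run(t, np.full((len(t), 2), 0.1), ["W1", "W2"])
        run, report = apply_qc_filters(run, manual_exclusions={"W2": "contaminated"})
        assert run.qc_flags["W2"] == "contaminated"
        short = _make_run(np.arange(0, 30, 2.0), np.full((15, 1), 0.1), ["W1"])
        with pytest.raises(ValueError):
            apply_qc_filters(short)


class TestGrowthRate:
    def test_noiseless_exponential_recovered_exactly(self):
        # cell signal at inoculation (~1e-9 OD) is far below the background,
        # as on a real plate, so the corrected trace is purely exponential
        t_min = np.arange(0, 641, 2.0)
        od = 0.1 + 1e-9 * np.exp(1.8 * t_min / 60.0)
        run = subtract_background(_make_run(t_min, od[:, None], ["W1"]))
        rates = log_window_growth_rate(run, od_threshold=0.03, window=30)
        assert rates["pooled_rate"] == pytest.approx(1.8, abs=1e-6)

    def test_recovery_with_multiplicative_noise(self):
        rng = np.random.default_rng(3)
        t_min = np.arange(0, 541, 2.0)
        t_h = t_min / 60.0
        cols = []
        for _ in range(24):
            clean = 1e-8 * np.exp(2.0 * t_h)
            cols.append(0.1 + clean * rng.lognormal(0, 0.01, size=len(t_h)))
        run = _make_run(t_min, np.column_stack(cols), [f"W{i}" for i in range(24)])
        run = subtract_background(run)
        rates = log_window_growth_rate(run, od_threshold=0.03, window=30)
        assert rates["pooled_rate"] == pytest.approx(2.0, rel=0.02)

    def test_threshold_position_changes_rate_direction(self):
        """On a saturating curve the apparent rate falls with the threshold."""
        t_min = np.arange(0, 601, 2.0)
        t_h = t_min / 60.0
        # logistic growth: slope decays as OD approaches capacity
        od = 0.1 + 0.3 / (1 + np.exp(-2.0 * (t_h - 5.0)))
        run = _make_run(t_min, od[:, None], ["W1"])
        run = subtract_background(run)
        r_low = log_window_growth_rate(run, od_threshold=0.02)["pooled_rate"]
        r_mid = log_window_growth_rate(run, od_threshold=0.03)["pooled_rate"]
        r_high = log_window_growth_rate(run, od_threshold=0.05)["pooled_rate"]
        assert r_low > r_mid > r_high

    def test_window_before_start_raises(self):
        t_min = np.arange(0, 121, 2.0)
        od = 0.1 + 0.05 * np.exp(5.0 * t_min / 60.0)  # crosses almost at once
        run = subtract_background(_make_run(t_min, od[:, None], ["W1"]))
        with pytest.raises(ValueError, match="window"):
            log_window_growth_rate(run, od_threshold=0.06, window=30)


class TestTsdVsThreshold:
    def test_deterministic_identical_wells_have_zero_tsd(self):
        t_min = np.arange(0, 301, 2.0)
        od = 0.1 + 0.001 * np.exp(1.8 * t_min / 60.0)
        run = subtract_background(
            _make_run(t_min, np.tile(od, (8, 1)).T, [f"W{i}" for i in range(8)])
        )
        table = tsd_vs_threshold(run, thresholds=[0.01, 0.05, 0.2], n_boot=100)
        assert np.allclose(table["tsd_hours"], 0.0, atol=1e-12)

    def test_sbp_fixture_flat_and_bounded_below(self):
        """Stochastic-inoculation fixture: TSD flat across OD 0.01–0.3 and
        at least the simple-birth-process floor at matched mu, n0."""
        cfg = FixtureConfig(
            growth_model="sbp", mu=1.8, inoculum_kind="exact", inoculum_value=2,
            wells_per_group=60, noise_sd=0.001, seed=11, horizon=14.0,
        )
        run, _ = generate_plate(cfg)
        run = subtract_background(run)
        table = tsd_vs_threshold(run, thresholds=np.geomspace(0.01, 0.3, 6), n_boot=100)
        tsds = table["tsd_hours"].to_numpy()
        assert tsds.max() / tsds.min() < 1.3
        floor = 1.0 / (1.8 * math.sqrt(2))
        se = tsds.mean() / math.sqrt(2 * (60 - 1))
        assert tsds.min() >= floor - 3 * se


class TestStandardCurve:
    def test_two_point_interpolation(self):
        curve = fit_standard_curve([0.03, 0.6], [1.4e7, 2.8e8])
        assert curve.to_cfu(0.03) == pytest.approx(1.4e7)
        assert curve.to_cfu(0.6) == pytest.approx(2.8e8)

    def test_noisy_proportionality_recovered(self, rng):
        slope = 4.67e8
        od = np.linspace(0.02, 0.6, 30)
        cfu = slope * od * rng.lognormal(0, 0.03, size=30)
        curve = fit_standard_curve(od, cfu)
        assert curve.slope == pytest.approx(slope, rel=0.05)

    def test_out_of_range_warns_and_degenerate_rejects(self):
        curve = StandardCurve(slope=4.67e8, intercept=0.0, od_range=(0.01, 0.6))
        with pytest.warns(UserWarning):
            curve.to_cfu(0.8)
        with pytest.raises(ValueError):
            fit_standard_curve([0.1, 0.1, 0.1], [1e7, 2e7, 3e7])


class TestLagPhase:
    curve = StandardCurve(slope=DEFAULT_OD_PER_CFU**-1, intercept=0.0)

    def _delta(self, cfg, n0):
        run, _ = generate_plate(cfg)
        run = subtract_background(run)
        report = lag_phase_check(
            run, self.curve, mu=cfg.mu, n0_by_group={run.groups()[0]: n0},
            od_threshold=0.03,
        )
        return float(report["delta_hours"].iloc[0])

    def test_deterministic_fixture_delta_zero(self):
        cfg = FixtureConfig(
            growth_model="deterministic", mu=1.8, inoculum_kind="exact",
            inoculum_value=5, noise_sd=0.0, wells_per_group=4, seed=0,
        )
        assert abs(self._delta(cfg, 5)) < 2.5 / 60.0  # within ~one read step

    def test_sbp_mean_crossing_lags_deterministic_prediction(self):
        """For exact single-cell inocula the SBP mean FPT exceeds the
        deterministic ln(Omega)/mu by ~Euler-gamma/mu, so delta is slightly
        negative for a zero-lag stochastic fixture."""
        from scipy.special import digamma

        cfg = FixtureConfig(
            growth_model="sbp", mu=1.8, inoculum_kind="exact", inoculum_value=1,
            noise_sd=0.0, wells_per_group=40, seed=5,
        )
        delta = self._delta(cfg, 1)
        omega = 0.03 / cfg.od_per_cfu
        expected = -(digamma(omega) - digamma(1) - math.log(omega)) / 1.8
        se = (1 / 1.8) / math.sqrt(40)  # TSD ~ 1/(mu sqrt(n0))
        assert delta < 0
        assert delta == pytest.approx(expected, abs=4 * se)

    def test_planted_lag_shifts_delta(self):
        base = dict(
            growth_model="deterministic", mu=1.8, inoculum_kind="exact",
            inoculum_value=5, noise_sd=0.0, wells_per_group=4, seed=0,
        )
        no_lag = self._delta(FixtureConfig(**base), 5)
        lagged = self._delta(FixtureConfig(**base, lag_minutes=60.0), 5)
        assert no_lag - lagged == pytest.approx(1.0, abs=0.05)  # ~60 min

    def test_threshold_outside_calibration_raises(self):
        cfg = FixtureConfig(noise_sd=0.0, wells_per_group=4, seed=0,
                            growth_model="deterministic", inoculum_kind="exact",
                            inoculum_value=5)
        run, _ = generate_plate(cfg)
        run = subtract_background(run)
        with pytest.raises(ValueError):
            lag_phase_check(run, self.curve, 1.8, {"g": 5}, od_threshold=0.9)


class TestEndToEnd:
    def test_parameter_recovery_and_unit_collapse(self):
        """Pipeline recovers the generating rate within 3% and TSDs taken at
        two different rates collapse in division-time units."""
        tsd_div_units = {}
        for mu, seed in [(0.8, 21), (1.8, 22)]:
            cfg = FixtureConfig(
                growth_model="sbp", mu=mu, inoculum_kind="exact", inoculum_value=3,
                wells_per_group=60, noise_sd=0.0, seed=seed,
                horizon=24.0 if mu < 1 else 12.0,
            )
            run, truth = generate_plate(cfg)
            run = subtract_background(run)
            rates = log_window_growth_rate(run, od_threshold=0.03)
            assert rates["pooled_rate"] == pytest.approx(mu, rel=0.03)
            table = tsd_vs_threshold(run, thresholds=[0.05], n_boot=300, seed=1)
            tsd_h = float(table["tsd_hours"].iloc[0])
            tsd_div_units[mu] = tsd_h * mu / math.log(2)
        a, b = tsd_div_units.values()
        # both should sit near the SBP value 1/sqrt(3) division times
        se = (a + b) / 2 / math.sqrt(2 * 59)
        assert abs(a - b) < 4 * math.sqrt(2) * se
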