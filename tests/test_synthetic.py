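"""Synthetic station-season generator: determinism, components, recovery."""

from datetime import timedelta

import numpy as np
import pytest

from soilvar.model import VAR
from soilvar.process import VARError, VARProcess
from soilvar.series import SeriesError, seasonal_difference
from soilvar.synthetic import (
    IrrigationEvent,
    SyntheticConfig,
    compose_deterministic,
    generate_dataset,
    inject_irrigation_events,
    simulate_var,
)

from .conftest import flat_depth_config, make_hourly


class TestSimulateVar:
    def test_noiseless_zero_system_stays_at_zero(self):
        y = simulate_var(np.array([[[0.5, 0.0], [0.0, 0.5]]]),
                         np.zeros(2), np.zeros((2, 2)), T=50, seed=1)
        assert np.all(y == 0.0)

    def test_sample_mean_matches_stationary_closed_form(self):
        coefs = np.array([[[0.5, 0.1], [0.0, 0.3]]])
        intercept = np.array([1.0, -0.5])
        proc = VARProcess(coefs, intercept=intercept, sigma=np.eye(2))
        y = proc.simulate(50_000, seed=4)
        mu = proc.mean()
        # 3 standard errors of the sample mean of an AR-correlated series
        se = 3 * y.std(axis=0) / np.sqrt(50_000 / 10)
        assert np.all(np.abs(y.mean(axis=0) - mu) < se)

    def test_lag1_autocovariance_matches_yule_walker(self, var1_process):
        y = var1_process.simulate(50_000, seed=6)
        yc = y - y.mean(axis=0)
        g1_sample = yc[1:].T @ yc[:-1] / (len(y) - 1)
        g1_true = var1_process.stationary_acov(1)[1]
        np.testing.assert_allclose(g1_sample, g1_true, atol=0.05)

    def test_unstable_coefficients_rejected_unless_overridden(self):
        bad = np.array([[[1.05, 0.0], [0.0, 0.5]]])
        with pytest.raises(VARError, match="unstable"):
            simulate_var(bad, np.zeros(2), np.eye(2), T=10, seed=0)
        y = simulate_var(bad, np.zeros(2), 0.0 * np.eye(2), T=5, seed=0,
                         burn_in=0, allow_unstable=True)
        assert y.shape == (5, 2)

    def test_deterministic_given_seed(self, var1_process):
        a = var1_process.simulate(100, seed=9)
        b = var1_process.simulate(100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestDeterministicComponent:
    def test_zero_amplitude_flat_trend_is_constant(self, var1_process):
        dc = flat_depth_config(10, var1_process)
        dc = type(dc)(**{**dc.__dict__, "temp_amplitude": 0.0})
        cfg = SyntheticConfig(days=10, depths=(dc,), irrigation_events=(), seed=0)
        det = compose_deterministic(cfg, 10, "temperature")
        assert np.allclose(det, dc.temp_baseline)

    def test_seasonal_difference_annihilates_flat_trend_component(self, var1_process):
        cfg = SyntheticConfig(days=10, depths=(flat_depth_config(10, var1_process),),
                              irrigation_events=(), seed=0)
        det = compose_deterministic(cfg, 10, "temperature")
        assert np.allclose(det[24:] - det[:-24], 0.0, atol=1e-12)

    def test_linear_trend_differences_to_24_times_slope(self, var1_process):
        dc = flat_depth_config(10, var1_process)
        slope = 0.003
        dc = type(dc)(**{**dc.__dict__,
                         "moist_trend": ((0.0, 0.0), (1e6, slope * 1e6))})
        cfg = SyntheticConfig(days=10, depths=(dc,), irrigation_events=(), seed=0)
        det = compose_deterministic(cfg, 10, "moisture")
        np.testing.assert_allclose(det[24:] - det[:-24], 24 * slope, atol=1e-9)


class TestIrrigation:
    def test_no_events_leaves_series_unchanged(self):
        s = make_hourly(np.full(48, 25.0))
        assert inject_irrigation_events(s, []) is s

    def test_jump_and_half_life_arithmetic(self):
        s = make_hourly(np.full(300, 25.0))
        ev = IrrigationEvent(s.time(100), jump=5.0, affected_depths=(10,), half_life=96.0)
        out = inject_irrigation_events(s, [ev])
        assert out.values[99] == 25.0
        assert out.values[100] == pytest.approx(30.0)
        assert out.values[196] == pytest.approx(27.5)  # one half-life later

    def test_unaffected_depth_and_variable_untouched(self):
        ev = IrrigationEvent(make_hourly(np.zeros(2)).time(1), jump=5.0,
                             affected_depths=(30,))
        s_t = make_hourly(np.full(48, 10.0), variable="temperature", depth=30)
        s_m = make_hourly(np.full(48, 25.0), depth=10)
        assert np.all(inject_irrigation_events(s_t, [ev]).values == 10.0)
        assert np.all(inject_irrigation_events(s_m, [ev]).values == 25.0)

    def test_event_outside_range_is_an_error(self):
        s = make_hourly(np.full(48, 25.0))
        ev = IrrigationEvent(s.start + timedelta(days=30), jump=1.0,
                             affected_depths=(10,))
        with pytest.raises(SeriesError, match="range"):
            inject_irrigation_events(s, [ev])


class TestGenerateDataset:
    def test_same_config_and_seed_is_bit_identical(self):
        a = generate_dataset(SyntheticConfig(days=20, seed=5))
        b = generate_dataset(SyntheticConfig(days=20, seed=5))
        for key in a.series:
            np.testing.assert_array_equal(a.series[key].values, b.series[key].values)

    def test_outputs_respect_hourly_grid_and_ranges(self):
        ds = generate_dataset(SyntheticConfig(days=30, seed=1))
        assert len(ds.series) == 6
        for (variable, depth), s in ds.series.items():
            assert s.variable == variable and s.depth == depth
            assert len(s) == 30 * 24  # construction enforces range invariants

    def test_differencing_recovers_the_var_truth_exactly(self, var1_process):
        """With flat trend and no events, the deseasonalized pair IS the
        (centered) VAR sample the generator drew."""
        proc = VARProcess(var1_process.coefs, sigma=0.01 * np.eye(2),
                          labels=("MCSD10", "STSD10"))
        cfg = SyntheticConfig(days=40, depths=(flat_depth_config(10, proc),),
                              irrigation_events=(), seed=13)
        ds = generate_dataset(cfg)
        child = np.random.SeedSequence(13).spawn(1)[0]
        v = proc.simulate(cfg.n_hours, seed=np.random.default_rng(child))
        v = v - proc.mean()
        for variable, col in (("moisture", 0), ("temperature", 1)):
            d = seasonal_difference(ds.series[(variable, 10)])
            np.testing.assert_allclose(d.values, v[24:, col], atol=1e-9)

    def test_end_to_end_coefficient_recovery(self):
        """Pipeline fit on generated data recovers the topsoil truth:
        averaged over seeds to beat down near-unit-root sampling noise.
        Uses the generator's range-calibrated innovation scale (the
        coefficient estimates are invariant to it)."""
        truth = SyntheticConfig(seed=0).depth_config(10).var_process
        ests = []
        for seed in range(12):
            cfg = SyntheticConfig(days=160,
                                  depths=(flat_depth_config(10, truth),),
                                  irrigation_events=(), seed=seed)
            ds = generate_dataset(cfg)
            mc = seasonal_difference(ds.series[("moisture", 10)])
            st = seasonal_difference(ds.series[("temperature", 10)])
            ests.append(VAR.from_pair(mc, st).fit(5).coefs)
        err = np.abs(np.mean(ests, axis=0) - truth.coefs).max()
        assert err < 0.05

    def test_one_way_coupling_is_detected_directionally(self):
        """Moisture drives temperature only: Granger Yes/No in >= 95% of seeds."""
        from soilvar.granger import granger_causality

        proc = VARProcess(np.array([[[0.6, 0.0], [0.25, 0.5]]]),
                          sigma=0.01 * np.eye(2), labels=("MCSD10", "STSD10"))
        ok = 0
        N = 40
        for seed in range(N):
            cfg = SyntheticConfig(days=80, depths=(flat_depth_config(10, proc),),
                                  irrigation_events=(), seed=seed)
            ds = generate_dataset(cfg)
            mc = seasonal_difference(ds.series[("moisture", 10)])
            st = seasonal_difference(ds.series[("temperature", 10)])
            ok += (granger_causality(st, mc, 1).causes(0.05)
                   and not granger_causality(mc, st, 1).causes(0.01))
        assert ok >= 0.95 * N

    def test_wide_csv_emission_is_readable_by_ingest(self, tmp_path):
        from soilvar.io import read_hourly_table

        ds = generate_dataset(SyntheticConfig(days=15, seed=2))
        path = tmp_path / "synth.csv"
        ds.to_csv(path)
        back = read_hourly_table(path)
        assert set(back) == set(ds.series)
        np.testing.assert_allclose(
            back[("moisture", 30)].values, ds.series[("moisture", 30)].values,
            atol=1e-9,
        )
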