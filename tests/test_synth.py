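"""Synthetic-data generator tests: determinism, noise-free identities,
maturation lag, hydration mass balance."""

import numpy as np
import pytest

import crossfeed as cf
from crossfeed.synth import HYDRATION_GAIN, _first_order_lag


class TestNoiseModel:
    def test_invalid_noise_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.NoiseModel(od_sd=-0.01)
        with pytest.raises(cf.ValidationError):
            cf.NoiseModel(evaporation_rate=0.02)


class TestGeneratePlateReader:
    def test_noise_free_signals_proportional_to_trajectory(self):
        scen = cf.Scenario(t_end=48.0)
        series = cf.generate_plate_reader(scen, maturation_halftime_h=0.0)
        traj = cf.simulate(scen)
        assert np.allclose(series.od600, traj.total)
        assert np.allclose(series.gfp_au, 1000.0 * traj.X)
        assert np.allclose(series.mscarlet_au, 800.0 * traj.G)

    def test_seeded_determinism(self):
        noise = cf.NoiseModel(od_sd=0.01, fluor_sd=10.0, seed=7)
        a = cf.generate_plate_reader(cf.Scenario(t_end=24.0), noise=noise)
        b = cf.generate_plate_reader(cf.Scenario(t_end=24.0), noise=noise)
        assert np.array_equal(a.od600, b.od600)
        assert np.array_equal(a.gfp_au, b.gfp_au)
        assert np.array_equal(a.mscarlet_au, b.mscarlet_au)
        c = cf.generate_plate_reader(
            cf.Scenario(t_end=24.0), noise=cf.NoiseModel(od_sd=0.01, fluor_sd=10.0, seed=8)
        )
        assert not np.array_equal(a.od600, c.od600)

    def test_mscarlet_first_order_maturation_lag(self):
        """The filtered red signal lags biomass and converges to yield*G
        once G is steady, with the closed-form first-order step response."""
        t = np.arange(0.0, 10.001, 0.1)
        step = np.where(t > 0, 1.0, 0.0)
        halftime = 0.67
        lagged = _first_order_lag(t, step, halftime)
        k = np.log(2) / halftime
        expected = 1 - (1 - step[0]) * np.exp(-k * t)
        # discrete filter vs continuous response: agreement to the step size
        assert np.allclose(lagged[1:], expected[1:], atol=0.05)
        assert lagged[-1] == pytest.approx(1.0, abs=1e-3)
        series = cf.generate_plate_reader(
            cf.Scenario(t_end=200.0), maturation_halftime_h=halftime
        )
        traj = cf.simulate(cf.Scenario(t_end=200.0))
        # allow for sub-ppm adaptive-solver wiggle in the plateau
        assert np.all(series.mscarlet_au <= 800.0 * traj.G + 1e-2)
        assert series.mscarlet_au[-1] == pytest.approx(800.0 * traj.G[-1], rel=1e-3)

    def test_evaporation_concentrates_late_signals(self):
        noise = cf.NoiseModel(evaporation_rate=0.005, evaporation_start_h=48.0)
        dry = cf.generate_plate_reader(cf.Scenario(), noise=noise)
        wet = cf.generate_plate_reader(cf.Scenario())
        early = dry.t <= 48.0
        assert np.allclose(dry.od600[early], wet.od600[early])
        assert np.all(dry.od600[~early] >= wet.od600[~early])
        assert dry.od600[-1] == pytest.approx(
            wet.od600[-1] * 1.005 ** (dry.t[-1] - 48.0)
        )


class TestGenerateHplc:
    def test_full_hydrolysis_glucose_plateau(self):
        series = cf.generate_hplc(
            {"cellobiose": 1.0}, {"cellobiose": 0.014}, t_end=200.0, n_points=50
        )
        assert series.cellobiose[-1] == 0.0
        assert series.glucose[-1] == pytest.approx(360.32 / 342.30, abs=1e-6)
        assert series.glucose[-1] == pytest.approx(1.0526, abs=1e-4)

    def test_zero_rates_keep_series_constant(self):
        series = cf.generate_hplc({"cellobiose": 2.0, "xylobiose": 1.5}, {})
        assert np.all(series.cellobiose == 2.0)
        assert np.all(series.xylobiose == 1.5)
        assert np.all(series.glucose == 0.0) and np.all(series.xylose == 0.0)

    def test_depletion_hits_zero_at_predicted_time(self):
        series = cf.generate_hplc(
            {"cellobiose": 2.0}, {"cellobiose": 0.014}, t_end=160.0, n_points=801
        )
        t_zero = series.t[np.nonzero(series.cellobiose == 0.0)[0][0]]
        assert t_zero == pytest.approx(2.0 / 0.014, abs=0.2)

    def test_mass_balance_exact_at_zero_noise(self):
        series = cf.generate_hplc(
            {"cellobiose": 2.0, "xylobiose": 2.0},
            {"cellobiose": 0.014, "xylobiose": 0.006},
            t_end=48.0,
            n_points=16,
        )
        for di, mono in (("cellobiose", "glucose"), ("xylobiose", "xylose")):
            d = getattr(series, di)
            m = getattr(series, mono)
            assert np.allclose(m, (d[0] - d) * HYDRATION_GAIN[di], atol=1e-12)

    def test_consumption_draws_down_monosaccharide(self):
        series = cf.generate_hplc(
            {"cellobiose": 2.0},
            {"cellobiose": 0.1},
            consumption_rates_g_per_l_h={"glucose": 0.05},
            t_end=30.0,
            n_points=31,
        )
        free = cf.generate_hplc(
            {"cellobiose": 2.0}, {"cellobiose": 0.1}, t_end=30.0, n_points=31
        )
        assert np.all(series.glucose <= free.glucose + 1e-12)
        assert np.all(series.glucose >= 0.0)

    def test_seeded_determinism(self):
        kwargs = dict(
            initial_disaccharides_g_per_l={"cellobiose": 2.0},
            conversion_rates_g_per_l_h={"cellobiose": 0.014},
            noise_sd=0.02,
        )
        a = cf.generate_hplc(**kwargs, seed=3)
        b = cf.generate_hplc(**kwargs, seed=3)
        assert np.array_equal(a.cellobiose, b.cellobiose)
        assert np.array_equal(a.glucose, b.glucose)


class TestCalibrationFixture:
    def test_noise_free_yield_refit_is_exact(self):
        fx = cf.generate_calibration_fixture("CP-X", "gfp", yield_au_per_od=1000.0)
        slope = np.polyfit(fx.od600, fx.gfp_au, 1)[0]
        assert slope == pytest.approx(1000.0, rel=1e-12)

    def test_noisy_yield_refit_within_two_percent(self):
        fx = cf.generate_calibration_fixture(
            "CP-X", "gfp", n_points=40, noise_sd_au=20.0, seed=21, yield_au_per_od=1000.0
        )
        slope = np.polyfit(fx.od600, fx.gfp_au, 1)[0]
        assert slope == pytest.approx(1000.0, rel=0.02)

    def test_seeded_fixture_reproducible_and_min_points_enforced(self):
        a = cf.generate_calibration_fixture("CP-G", "mscarlet", noise_sd_au=5.0, seed=2)
        b = cf.generate_calibration_fixture("CP-G", "mscarlet", noise_sd_au=5.0, seed=2)
        assert np.array_equal(a.mscarlet_au, b.mscarlet_au)
        assert np.all(a.gfp_au == 0.0)  # single-strain well
        with pytest.raises(cf.ValidationError):
            cf.generate_calibration_fixture("CP-X", "gfp", n_points=5)


def test_growth_observations_deterministic_and_clipped():
    scen = cf.Scenario(t_end=24.0)
    a = cf.generate_growth_observations(scen, od_sd=0.05, seed=6, n_replicates=2)
    b = cf.generate_growth_observations(scen, od_sd=0.05, seed=6, n_replicates=2)
    for x, y in zip(a, b):
        assert np.array_equal(x.od_total, y.od_total)
        assert np.array_equal(x.od_x, y.od_x)
        assert np.all(x.od_total >= 0) and np.all(x.od_x >= 0)
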