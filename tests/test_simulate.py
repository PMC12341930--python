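"""Integration tests: ODE solution, scenario construction, variant battery."""

import dataclasses

import numpy as np
import pytest

import crossfeed as cf
from crossfeed.model import derivatives


def rk4_oracle(scenario: cf.Scenario, dt: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Independent fixed-step classical RK4 integration on the output grid."""

    def f(y):
        return np.array(
            derivatives(
                cf.ConsortiumState(max(y[0], 0.0), max(y[1], 0.0)),
                scenario.params,
                scenario.scaling,
            )
        )

    t_grid = scenario.t_grid
    y = np.array([scenario.initial.X, scenario.initial.G])
    out = [y.copy()]
    t = 0.0
    for t_next in t_grid[1:]:
        while t < t_next - 1e-12:
            h = min(dt, t_next - t)
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out.append(y.copy())
    arr = np.array(out)
    return arr[:, 0], arr[:, 1]


class TestSimulate:
    def test_adaptive_solver_matches_rk4_oracle(self):
        scen = cf.Scenario(t_end=48.0, dt_out=4.0)
        traj = cf.simulate(scen)
        X_ref, G_ref = rk4_oracle(scen)
        assert np.allclose(traj.X, X_ref, atol=1e-5)
        assert np.allclose(traj.G, G_ref, atol=1e-5)

    def test_rk4_oracle_under_scaling_scenario(self):
        scen = cf.Scenario(
            scaling=cf.ScalingFactors(alpha_Dx=0.6, alpha_Dg=1.4, alpha_Bx=1.3),
            t_end=48.0,
            dt_out=6.0,
        )
        traj = cf.simulate(scen)
        X_ref, G_ref = rk4_oracle(scen)
        assert np.allclose(traj.X, X_ref, atol=1e-5)
        assert np.allclose(traj.G, G_ref, atol=1e-5)

    def test_baseline_reaches_fitted_carrying_capacity(self):
        """The reference fit saturates at total OD = K = 0.82 by 300 h."""
        traj = cf.simulate(cf.Scenario(t_end=300.0))
        assert traj.total[-1] == pytest.approx(0.82, abs=1e-3)

    def test_low_cellobiose_halves_the_capacity(self):
        scen = cf.Scenario(scaling=cf.ScalingFactors(alpha_Dx=0.5), t_end=300.0)
        traj = cf.simulate(scen)
        assert traj.total[-1] == pytest.approx(0.41, abs=1e-3)

    @pytest.mark.parametrize("initial", [(0.05, 0.0), (0.0, 0.05)])
    def test_mutual_obligacy_freezes_trajectories(self, initial):
        scen = cf.Scenario(initial=cf.ConsortiumState(*initial), t_end=24.0)
        traj = cf.simulate(scen)
        assert np.allclose(traj.X, initial[0], atol=1e-9)
        assert np.allclose(traj.G, initial[1], atol=1e-9)

    def test_total_od_never_exceeds_scaled_capacity(self):
        for scaling in [cf.IDENTITY_SCALING, cf.ScalingFactors(0.6, 1.4, 1.0, 0.8)]:
            scen = cf.Scenario(scaling=scaling, t_end=300.0)
            traj = cf.simulate(scen)
            cap = scaling.alpha_K * scen.params.K
            assert traj.total.max() <= cap * (1 + 1e-6)

    def test_equilibrium_from_any_positive_start(self):
        for x0, g0 in [(0.001, 0.05), (0.2, 0.01), (0.05, 0.05)]:
            scen = cf.Scenario(initial=cf.ConsortiumState(x0, g0), t_end=300.0)
            traj = cf.simulate(scen)
            assert traj.total[-1] == pytest.approx(0.82, abs=1e-3)

    def test_burden_is_pathwise_monotone(self):
        """Raising alpha_Bx can only slow CP-X at every output time."""
        trajs = [
            cf.simulate(cf.Scenario(scaling=cf.ScalingFactors(alpha_Bx=b), t_end=72.0))
            for b in (0.5, 1.0, 2.0, 4.0)
        ]
        for slower, faster in zip(trajs[1:], trajs[:-1]):
            assert np.all(slower.X <= faster.X + 1e-9)

    def test_invalid_grid_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.Scenario(t_end=0.0)
        with pytest.raises(cf.ValidationError):
            cf.Scenario(dt_out=-0.5)


class TestScenarioHelpers:
    @pytest.mark.parametrize(
        "total,ratio,expected",
        [
            (0.02, 1, (0.01, 0.01)),
            (0.02, 10, (0.0182, 0.0018)),  # 10:1 in favour of CP-X
            (0.05, 4, (0.04, 0.01)),
        ],
    )
    def test_inoculation_ratio_split(self, total, ratio, expected):
        s = cf.inoculation_ratio_to_state(total, ratio)
        assert s.X == pytest.approx(expected[0], abs=5e-5)
        assert s.G == pytest.approx(expected[1], abs=5e-5)
        assert s.X + s.G == pytest.approx(total)

    def test_inoculation_rejects_nonpositive(self):
        with pytest.raises(cf.ValidationError):
            cf.inoculation_ratio_to_state(0.0, 1.0)
        with pytest.raises(cf.ValidationError):
            cf.inoculation_ratio_to_state(0.02, -1.0)

    @pytest.mark.parametrize(
        "cello,xylo,aDx,aDg",
        [(1.0, 1.0, 1.0, 1.0), (0.6, 1.4, 0.6, 1.4), (0.2, 1.8, 0.2, 1.8)],
    )
    def test_substrate_ratio_scaling(self, cello, xylo, aDx, aDg):
        s = cf.substrate_ratio_to_scaling(cello, xylo)
        assert s.alpha_Dx == pytest.approx(aDx)
        assert s.alpha_Dg == pytest.approx(aDg)
        assert s.alpha_Bx == 1.0 and s.alpha_Ex == 1.0

    def test_substrate_ratio_rejects_negative(self):
        with pytest.raises(cf.ValidationError):
            cf.substrate_ratio_to_scaling(-0.1, 1.0)


class TestBattery:
    def test_baseline_variant_summary(self):
        base = cf.Scenario(t_end=300.0)
        table = cf.scenario_battery(base, {"baseline": {}})
        assert len(table) == 1
        assert table.loc[0, "od_total_final"] == pytest.approx(0.82, abs=1e-3)

    def test_degradation_tag_variant_runs(self):
        """Weakened BglC: larger C_x, faster unburdened CP-X growth."""
        base = cf.Scenario()
        table = cf.scenario_battery(
            base,
            {
                "baseline": {},
                "bglc_degron": {"C_x": 0.08, "r_mx": 0.22},
                "ratio_10_to_1": {"X0": 0.0182, "G0": 0.0018},
            },
        )
        assert list(table["variant"]) == ["baseline", "bglc_degron", "ratio_10_to_1"]
        assert np.isfinite(table["od_total_final"]).all()
        assert np.isfinite(table["ratio_x_to_g_final"]).all()

    def test_empty_variant_list_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.scenario_battery(cf.Scenario(), {})

    def test_failing_variant_names_culprit(self):
        with pytest.raises(cf.ValidationError, match="bad_variant"):
            cf.scenario_battery(cf.Scenario(), {"bad_variant": {"nonsense_key": 1}})
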