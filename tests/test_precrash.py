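"""Kinematic pre-crash simulation: construction, AEB braking, oracles."""

import math

import numpy as np
import pytest

from aebrisk.precrash import (
    AEBConfig,
    VehicleGeometry,
    construct_initial_state,
    crash_risk_reduction,
    simulate,
    simulate_catalog,
)
from conftest import crossing_scenario

G = 9.81


def instant_brake_config(mu_g: float, **kwargs) -> AEBConfig:
    """AEB with negligible delay and effectively infinite ramp, so braking
    is a step to the friction limit mu_g (in m/s^2)."""
    return AEBConfig(brake_delay=1e-12, brake_gradient=1e9, mu_dry=mu_g / G, **kwargs)


class TestConstruction:
    def test_perpendicular_crossing_geometry(self):
        s = crossing_scenario(v_veh=36.0, v_vru=3.6, cp=0.0)
        state = construct_initial_state(s, VehicleGeometry(), lead_time=6.0)
        assert state.x_front == pytest.approx(-60.0)
        # SCPPL: pedestrian approaches from the left (+y), 6 m out
        assert state.ped_xy[0] == pytest.approx(0.0, abs=1e-12)
        assert state.ped_xy[1] == pytest.approx(6.0)

    def test_collision_point_lateral_offset(self):
        s = crossing_scenario(cp=25.0)
        state = construct_initial_state(s, VehicleGeometry(width=1.8), lead_time=6.0)
        # CP positive to the right = negative y; offset 25% of 1.8 m = 0.45 m
        y_meet = state.ped_xy[1] + state.ped_v[1] * 6.0
        assert y_meet == pytest.approx(-0.45)

    def test_unknown_conflict_situation_rejected(self):
        s = crossing_scenario(cs="SCPPL")
        object.__setattr__(s, "conflict_situation", "NOPE")
        with pytest.raises(KeyError):
            construct_initial_state(s, VehicleGeometry(), 4.0)


class TestBaseline:
    def test_baseline_reproduces_construction(self):
        s = crossing_scenario(v_veh=36.0, v_vru=3.6, cp=10.0)
        out = simulate(s, lead_time=6.0)
        assert out.collided
        assert out.t_coll == pytest.approx(6.0, abs=0.011)
        assert out.v_veh_coll == pytest.approx(36.0, abs=1e-9)
        assert out.collision_point == pytest.approx(10.0, abs=0.5)
        assert out.angle == pytest.approx(270.0)

    def test_baseline_collides_for_all_catalog_scenarios(self, small_catalog):
        outcomes = simulate_catalog(small_catalog, aeb=None)
        assert all(o.collided for o in outcomes)

    def test_standing_pedestrian_collides(self):
        out = simulate(crossing_scenario(v_veh=30.0, v_vru=0.0, cp=0.0))
        assert out.collided
        assert out.v_vru_coll == 0.0


class TestClosedFormBraking:
    """Constant-deceleration kinematics oracles at 30 km/h (8.333 m/s):
    braking from a gap of v0 * TTC_trigger = 8.333 m."""

    def test_avoidance_at_high_friction(self):
        # stopping distance v^2/(2a) = 4.34 m < 8.33 m gap
        out = simulate(crossing_scenario(v_veh=30.0), aeb=instant_brake_config(8.0))
        assert out.aeb_triggered
        assert not out.collided

    def test_residual_speed_at_low_friction(self):
        # v = sqrt(v0^2 - 2*4*gap) = 1.667 m/s = 6.0 km/h
        out = simulate(crossing_scenario(v_veh=30.0), aeb=instant_brake_config(4.0))
        assert out.collided
        assert out.v_veh_coll == pytest.approx(6.0, abs=0.5)

    def test_piecewise_delay_and_ramp_oracle(self):
        """Independent piecewise closed-form check with non-zero brake delay
        and finite ramp gradient."""
        v0 = 50.0 / 3.6
        delay, grad, mu_g = 0.2, 30.0, 6.0
        aeb = AEBConfig(brake_delay=delay, brake_gradient=grad, mu_dry=mu_g / G)
        out = simulate(crossing_scenario(v_veh=50.0), aeb=aeb)
        # oracle: gap = v0 * 1.0 s; integrate v(t) = v0 - Dv(t) until the
        # travelled distance reaches the gap
        gap = v0 * aeb.ttc_trigger
        dt = 1e-5
        t, x, v = 0.0, 0.0, v0
        while x < gap and v > 0:
            tb = t - delay
            dv = 0.0
            if tb > 0:
                t_r = mu_g / grad
                dv = 0.5 * grad * tb**2 if tb <= t_r else mu_g * tb - mu_g**2 / (2 * grad)
            v = max(v0 - dv, 0.0)
            x += v * dt
            t += dt
        expected_kmh = v * 3.6 if x >= gap else None
        if expected_kmh is None:
            assert not out.collided
        else:
            assert out.collided
            assert out.v_veh_coll == pytest.approx(expected_kmh, abs=0.5)


class TestInvariants:
    def test_collision_speed_never_exceeds_initial(self, small_catalog):
        outcomes = simulate_catalog(small_catalog, aeb=AEBConfig())
        by_id = {s.id: s for s in small_catalog}
        for o in outcomes:
            if o.collided:
                assert o.v_veh_coll <= by_id[o.scenario_id].v_veh0 + 1e-9

    def test_mu_monotonicity_on_speed_cp_grid(self):
        """Raising friction never increases the collision speed."""
        speeds = np.linspace(20.0, 65.0, 10)
        cps = np.linspace(-45.0, 45.0, 10)
        scenarios = [
            crossing_scenario(v_veh=v, v_vru=3.6, cp=cp, prob=0.01)
            for v in speeds for cp in cps
        ]
        prev = None
        for mu in (0.3, 0.5, 0.8):
            outcomes = simulate_catalog(scenarios, aeb=AEBConfig(mu_dry=mu))
            v_coll = np.array(
                [o.v_veh_coll if o.collided else 0.0 for o in outcomes]
            )
            if prev is not None:
                assert np.all(v_coll <= prev + 1e-6)
            prev = v_coll

    def test_time_step_halving_stability(self):
        """Collision speeds move by < 0.5 km/h when the step is halved."""
        scenarios = [
            crossing_scenario(v_veh=v, v_vru=u, cp=cp, prob=0.1)
            for v, u, cp in [(30, 3.6, 0), (45, 5, 20), (60, 2, -20), (25, 8, 40)]
        ]
        aeb = AEBConfig(mu_dry=0.4)
        full = simulate_catalog(scenarios, aeb=aeb)
        half = simulate_catalog(
            scenarios, aeb=AEBConfig(mu_dry=0.4, time_step=0.005)
        )
        for a, b in zip(full, half):
            assert a.collided == b.collided
            if a.collided:
                assert abs(a.v_veh_coll - b.v_veh_coll) < 0.5


class TestCrashRiskReduction:
    def test_weighted_sum(self):
        s1 = crossing_scenario(v_veh=30.0, prob=0.75)
        s2 = crossing_scenario(v_veh=40.0, prob=0.25)
        outcomes = [
            simulate(s1),  # baseline: collides
            type(simulate(s2))(scenario_id=s2.id, collided=False),
        ]
        assert crash_risk_reduction([s1, s2], outcomes) == pytest.approx(25.0)

    def test_bounds(self, small_catalog):
        baseline = simulate_catalog(small_catalog, aeb=None)
        assert crash_risk_reduction(small_catalog, baseline) == pytest.approx(0.0)
        avoided = [type(o)(scenario_id=o.scenario_id, collided=False) for o in baseline]
        assert crash_risk_reduction(small_catalog, avoided) == pytest.approx(100.0)

    def test_missing_outcomes_error(self, small_catalog):
        with pytest.raises(ValueError, match="missing outcomes"):
            crash_risk_reduction(small_catalog, [])
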