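"""Kinematic pre-crash simulation with a generic AEB system.

Each virtual testing scenario is simulated twice in a planar world: a
baseline run (no driver reaction, no system intervention) and a run with a
generic autonomous-emergency-braking system.  The vehicle drives straight
along +x; the pedestrian walks a straight path whose crossing angle comes
from the conflict-situation template.  The start state is constructed such
that, at constant speeds, the pedestrian centre meets the vehicle front
plane at the scenario's target collision point exactly ``lead_time``
seconds after start.

The AEB model follows the generic prospective-assessment recipe: a
geometric sensor (range, field of view, azimuth quantization) must see the
full pedestrian disc for a confirmation time; braking is commanded when the
time to collision (TTC, constant-velocity extrapolation) drops below the
trigger threshold; after a brake delay the deceleration ramps at the brake
gradient up to the friction limit mu*g of the current road condition.

Coordinates: x forward, y to the vehicle's left.  The collision point CP is
positive toward the vehicle's right, so CP = -y / width * 100.  The
collision angle A is the pedestrian heading minus the vehicle heading,
counter-clockwise, wrapped to [0, 360).  Contact is registered when the
pedestrian centre crosses the vehicle front plane within the front-edge
span (half width plus pedestrian radius); contact time and speed are
interpolated within the time step, which keeps the collision speed
essentially free of discretization error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import VirtualTestingScenario

G = 9.81  # gravitational acceleration [m/s^2]
KMH = 1.0 / 3.6  # km/h -> m/s

#: pedestrian heading per conflict situation, degrees CCW relative to the
#: vehicle heading.  SCPP{L,R}: straight perpendicular crossing from
#: left/right; SCPO{L,R}: oblique crossing facing the oncoming vehicle;
#: TAPPL: turning-across-path approximated by its collision-local straight
#: equivalent.  All headings have a non-positive forward component so the
#: vehicle always closes on the pedestrian and the constructed baseline
#: meeting is a genuine front-plane crossing.
DEFAULT_TEMPLATES: dict[str, float] = {
    "SCPPL": 270.0,
    "SCPPR": 90.0,
    "SCPOL": 225.0,
    "SCPOR": 135.0,
    "TAPPL": 250.0,
}


@dataclass
class AEBConfig:
    """Generic AEB system parameters."""

    sensor_range: float = 60.0  # [m]
    fov: float = 60.0  # total azimuth opening angle [deg]
    sensor_setback: float = 0.25  # behind the most frontal point [m]
    confirm_time: float = 0.150  # continuous-detection time before confirmation [s]
    ttc_trigger: float = 1.0  # braking commanded at TTC <= trigger [s]
    azimuth_resolution: float = 0.5  # [deg]
    time_step: float = 0.010  # [s]
    brake_delay: float = 0.15  # [s]
    brake_gradient: float = 35.0  # deceleration ramp rate [m/s^3]
    mu_dry: float = 0.8
    mu_non_dry: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sensor_range", "fov", "confirm_time", "ttc_trigger",
                     "azimuth_resolution", "time_step", "brake_gradient",
                     "mu_dry", "mu_non_dry"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sensor_setback < 0 or self.brake_delay < 0:
            raise ValueError("sensor_setback and brake_delay must be non-negative")
        if self.fov >= 180.0:
            raise ValueError("fov must be below 180 degrees")
        steps = self.confirm_time / self.time_step
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("time_step must divide confirm_time")

    def mu(self, road_condition: str) -> float:
        return self.mu_dry if road_condition == "dry" else self.mu_non_dry


@dataclass
class VehicleGeometry:
    width: float = 1.8  # front width [m]
    front_to_cog: float = 2.2  # [m], informational
    pedestrian_radius: float = 0.3  # [m]

    def __post_init__(self) -> None:
        if self.width <= 0 or self.pedestrian_radius <= 0:
            raise ValueError("width and pedestrian_radius must be positive")


@dataclass(frozen=True)
class CollisionOutcome:
    """Result of one simulation run (baseline or with AEB)."""

    scenario_id: str
    collided: bool
    v_veh_coll: float | None = None  # [km/h]
    v_vru_coll: float | None = None  # [km/h]
    angle: float | None = None  # [deg], [0, 360)
    collision_point: float | None = None  # [%], [-50, 50]
    t_coll: float | None = None  # [s]
    aeb_triggered: bool = False

    def __post_init__(self) -> None:
        if self.collided:
            for name in ("v_veh_coll", "v_vru_coll", "angle", "collision_point"):
                if getattr(self, name) is None:
                    raise ValueError(f"collided outcome missing {name}")
        else:
            if self.v_veh_coll is not None:
                raise ValueError("avoided outcome must not carry collision fields")


@dataclass
class InitialState:
    """Constructed planar start state of one scenario."""

    x_front: float  # vehicle front-plane x [m]
    v_veh: float  # [m/s]
    ped_xy: tuple[float, float]  # [m]
    ped_v: tuple[float, float]  # [m/s]
    heading_deg: float  # pedestrian heading relative to vehicle [deg CCW]
    lead_time: float  # [s]


def construct_initial_state(
    s: VirtualTestingScenario,
    geom: VehicleGeometry,
    lead_time: float,
    templates: Mapping[str, float] | None = None,
) -> InitialState:
    """Place vehicle and pedestrian so that, at constant speeds, the
    pedestrian centre meets the front plane at the target collision point
    after exactly ``lead_time`` seconds."""
    templates = templates or DEFAULT_TEMPLATES
    if s.conflict_situation not in templates:
        raise KeyError(f"no trajectory template for conflict situation {s.conflict_situation!r}")
    theta = math.radians(templates[s.conflict_situation])
    v = s.v_veh0 * KMH
    u = s.v_vru0 * KMH
    y_star = -s.collision_point_target / 100.0 * geom.width
    ux, uy = u * math.cos(theta), u * math.sin(theta)
    return InitialState(
        x_front=-v * lead_time,
        v_veh=v,
        ped_xy=(-ux * lead_time, y_star - uy * lead_time),
        ped_v=(ux, uy),
        heading_deg=math.degrees(theta) % 360.0,
        lead_time=lead_time,
    )


def _brake_impulse(tb, delay: float, gradient: float, a_max) -> np.ndarray:
    """Velocity change accumulated ``tb`` seconds after the brake trigger:
    zero during the delay, then the integral of a deceleration ramping at
    ``gradient`` until it saturates at ``a_max``."""
    s = np.maximum(np.asarray(tb, dtype=float) - delay, 0.0)
    a_max = np.asarray(a_max, dtype=float)
    t_ramp = a_max / gradient
    return np.where(
        s <= t_ramp,
        0.5 * gradient * s**2,
        a_max * s - a_max**2 / (2.0 * gradient),
    )


def _effective_lead_times(
    v: np.ndarray, ux: np.ndarray, uy: np.ndarray, cp_y: np.ndarray,
    lead_time: float, geom: VehicleGeometry, aeb: AEBConfig | None,
) -> np.ndarray:
    """Per-scenario start lead time; with a sensor present the pedestrian
    must start outside sensor range, so slow vehicles start earlier."""
    T = np.full(v.shape, float(lead_time))
    if aeb is None:
        return T
    for _ in range(40):
        px = -ux * T
        py = cp_y - uy * T
        sx = -v * T - aeb.sensor_setback
        d = np.hypot(px - sx, py)
        inside = d <= aeb.sensor_range + geom.pedestrian_radius
        if not inside.any():
            break
        T[inside] *= 1.3
    else:
        raise ValueError("could not place pedestrian outside sensor range")
    return T


def simulate_catalog(
    scenarios: Sequence[VirtualTestingScenario],
    geom: VehicleGeometry | None = None,
    aeb: AEBConfig | None = None,
    templates: Mapping[str, float] | None = None,
    lead_time: float = 4.0,
    horizon_margin: float = 10.0,
    time_step: float | None = None,
) -> list[CollisionOutcome]:
    """Simulate every scenario (vectorized across the catalog).

    With ``aeb=None`` the baseline run is performed (constant speeds, which
    by construction ends in a collision at ``lead_time``).  Returns one
    outcome per input scenario, in input order.
    """
    geom = geom or VehicleGeometry()
    templates = templates or DEFAULT_TEMPLATES
    n = len(scenarios)
    if n == 0:
        return []
    dt = time_step if time_step is not None else (aeb.time_step if aeb else 0.010)

    theta = np.array([math.radians(templates[s.conflict_situation]) for s in scenarios])
    v0 = np.array([s.v_veh0 for s in scenarios]) * KMH
    u0 = np.array([s.v_vru0 for s in scenarios]) * KMH
    cp_y = np.array([-s.collision_point_target / 100.0 * geom.width for s in scenarios])
    mu = (
        np.array([aeb.mu(s.road_condition) for s in scenarios])
        if aeb
        else np.zeros(n)
    )
    ux, uy = u0 * np.cos(theta), u0 * np.sin(theta)
    T = _effective_lead_times(v0, ux, uy, cp_y, lead_time, geom, aeb)

    # state arrays
    x_f = -v0 * T
    v = v0.copy()
    px, py = -ux * T, cp_y - uy * T
    conf = np.zeros(n, dtype=int)
    detected = np.zeros(n, dtype=bool)
    t_detect = np.full(n, np.inf)
    triggered = np.zeros(n, dtype=bool)
    t_trig = np.full(n, np.inf)
    v_trig = np.zeros(n)
    active = np.ones(n, dtype=bool)
    collided = np.zeros(n, dtype=bool)
    out_v = np.full(n, np.nan)
    out_y = np.full(n, np.nan)
    out_t = np.full(n, np.nan)
    t_end = T + horizon_margin

    span = geom.width / 2.0 + geom.pedestrian_radius
    half_fov = math.radians((aeb.fov if aeb else 0.0) / 2.0)
    res = math.radians(aeb.azimuth_resolution) if aeb else 1.0
    conf_steps = int(round(aeb.confirm_time / dt)) if aeb else 0

    t = 0.0
    max_t = float(t_end.max())
    while active.any() and t <= max_t + dt:
        idx = np.nonzero(active)[0]
        if aeb is not None:
            # geometric sensor: full pedestrian disc inside the quantized FOV
            sx = x_f[idx] - aeb.sensor_setback
            dx, dy = px[idx] - sx, py[idx]
            d = np.hypot(dx, dy)
            with np.errstate(invalid="ignore"):
                half_w = np.arcsin(np.clip(geom.pedestrian_radius / np.maximum(d, 1e-12), 0.0, 1.0))
            ang = np.arctan2(dy, dx)
            q_lo = np.round((ang - half_w) / res) * res
            q_hi = np.round((ang + half_w) / res) * res
            in_view = (
                (d <= aeb.sensor_range)
                & (d > geom.pedestrian_radius)
                & (np.abs(q_lo) <= half_fov)
                & (np.abs(q_hi) <= half_fov)
            )
            conf[idx] = np.where(in_view, conf[idx] + 1, 0)
            newly_detected = (conf[idx] >= conf_steps) & ~detected[idx]
            t_detect[idx[newly_detected]] = t
            detected[idx] |= conf[idx] >= conf_steps
            # TTC: constant-velocity extrapolation of both participants
            closing = v[idx] - ux[idx]
            with np.errstate(divide="ignore", invalid="ignore"):
                ttc = np.where(closing > 1e-9, (px[idx] - x_f[idx]) / np.maximum(closing, 1e-9), np.inf)
            lat = py[idx] + uy[idx] * ttc
            ttc_valid = (ttc >= 0.0) & (np.abs(lat) <= geom.width / 2.0)
            fire = detected[idx] & ttc_valid & (ttc <= aeb.ttc_trigger) & ~triggered[idx]
            # back-date the trigger to the instant TTC crossed the threshold
            # (exact: speeds are constant pre-trigger), but never before the
            # detection was confirmed
            t_cross = t - np.maximum(aeb.ttc_trigger - ttc, 0.0)
            t_trig[idx[fire]] = np.maximum(t_cross[fire], t_detect[idx[fire]])
            v_trig[idx[fire]] = v[idx][fire]
            triggered[idx] |= fire
            # closed-form braked speed: v(t) = v_trig - integral of the
            # delay/ramp/saturation deceleration profile
            tb = (t + dt) - t_trig[idx]
            v_new = np.where(
                triggered[idx],
                np.maximum(
                    v_trig[idx]
                    - _brake_impulse(tb, aeb.brake_delay, aeb.brake_gradient, mu[idx] * G),
                    0.0,
                ),
                v[idx],
            )
        else:
            v_new = v[idx]
        x_f_new = x_f[idx] + 0.5 * (v[idx] + v_new) * dt
        px_new = px[idx] + ux[idx] * dt
        py_new = py[idx] + uy[idx] * dt

        # contact: pedestrian centre crosses the front plane inside the span
        qx_old = px[idx] - x_f[idx]
        qx_new = px_new - x_f_new
        crossing = (qx_old > 0.0) & (qx_new <= 0.0)
        s_frac = np.where(crossing, qx_old / np.maximum(qx_old - qx_new, 1e-12), 0.0)
        qy_star = py[idx] + uy[idx] * s_frac * dt
        hit = crossing & (np.abs(qy_star) <= span)
        hit_idx = idx[hit]
        collided[hit_idx] = True
        out_v[hit_idx] = v[idx][hit] + s_frac[hit] * (v_new[hit] - v[idx][hit])
        out_y[hit_idx] = qy_star[hit]
        out_t[hit_idx] = t + s_frac[hit] * dt
        active[hit_idx] = False

        # passed without contact, vehicle brought to a full stop, or horizon;
        # a full stop counts as avoidance (a residual pedestrian walk-in
        # against a stationary vehicle is not a vehicle crash)
        passed = crossing & ~hit
        stalled = (v_new <= 0.0) & ~hit
        timed_out = (t + dt) >= t_end[idx]
        active[idx[passed | stalled | timed_out]] = False

        v[idx], x_f[idx], px[idx], py[idx] = v_new, x_f_new, px_new, py_new
        t += dt

    heading_deg = np.degrees(theta) % 360.0
    outcomes: list[CollisionOutcome] = []
    for i, s in enumerate(scenarios):
        if collided[i]:
            outcomes.append(
                CollisionOutcome(
                    scenario_id=s.id,
                    collided=True,
                    v_veh_coll=float(out_v[i] / KMH),
                    v_vru_coll=float(s.v_vru0),
                    angle=float(heading_deg[i]),
                    collision_point=float(np.clip(-out_y[i] / geom.width * 100.0, -50.0, 50.0)),
                    t_coll=float(out_t[i]),
                    aeb_triggered=bool(triggered[i]),
                )
            )
        else:
            outcomes.append(
                CollisionOutcome(scenario_id=s.id, collided=False, aeb_triggered=bool(triggered[i]))
            )
    return outcomes


def simulate(
    s: VirtualTestingScenario,
    geom: VehicleGeometry | None = None,
    aeb: AEBConfig | None = None,
    templates: Mapping[str, float] | None = None,
    lead_time: float = 4.0,
    horizon_margin: float = 10.0,
    time_step: float | None = None,
) -> CollisionOutcome:
    """Simulate a single scenario (baseline when ``aeb`` is None)."""
    return simulate_catalog(
        [s], geom=geom, aeb=aeb, templates=templates, lead_time=lead_time,
        horizon_margin=horizon_margin, time_step=time_step,
    )[0]


def crash_risk_reduction(
    scenarios: Sequence[VirtualTestingScenario],
    outcomes: Sequence[CollisionOutcome],
) -> float:
    """Probability-weighted share of avoided scenarios, in percent."""
    by_id = {o.scenario_id: o for o in outcomes}
    missing = [s.id for s in scenarios if s.id not in by_id]
    if missing:
        raise ValueError(f"missing outcomes for scenarios: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    return 100.0 * sum(s.probability for s in scenarios if not by_id[s.id].collided)


OUTCOME_COLUMNS = [
    "id",
    "v_veh_coll_baseline_kmh", "cp_baseline_pct", "angle_baseline_deg",
    "v_vru_coll_kmh",
    "v_veh_coll_aeb_kmh", "cp_aeb_pct", "angle_aeb_deg",
]


def write_outcomes(
    baseline: Sequence[CollisionOutcome],
    with_aeb: Sequence[CollisionOutcome],
    path: str | Path,
) -> None:
    """Outcome table; avoided scenarios carry empty AEB collision fields."""
    aeb_by_id = {o.scenario_id: o for o in with_aeb}
    rows = []
    for b in baseline:
        a = aeb_by_id.get(b.scenario_id)
        rows.append(
            {
                "id": b.scenario_id,
                "v_veh_coll_baseline_kmh": b.v_veh_coll,
                "cp_baseline_pct": b.collision_point,
                "angle_baseline_deg": b.angle,
                "v_vru_coll_kmh": b.v_vru_coll,
                "v_veh_coll_aeb_kmh": a.v_veh_coll if a and a.collided else None,
                "cp_aeb_pct": a.collision_point if a and a.collided else None,
                "angle_aeb_deg": a.angle if a and a.collided else None,
            }
        )
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(path, index=False)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
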