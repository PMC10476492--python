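"""Synthetic accident data and a surrogate in-crash injury response.

The generator emits accident records drawn from a fully specified
probabilistic world — categorical severity / conflict-situation /
road-condition probabilities and per-stratum Weibull speed distributions —
so that every estimation stage can be validated against known parameters.
The surrogate injury response stands in for finite-element in-crash
simulations: each injury criterion's risk is a deterministic logistic
function of the collision-scenario coordinates (increasing in collision
speed), with anthropometry-specific coefficients that encode the
field-observed direction of sex differences (higher proximal-femur risk
for the average female, higher rib and skull fracture risk for the average
male).  A companion signal emitter produces half-sine head-acceleration
pulses and strain scalars so the signal-level injury chain can be
exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .accident_stats import AccidentRecord, WeibullParams
from .injury import ANTHROPOMETRIES, CRITERIA, Channel, InjuryRiskVector


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class GeneratorConfig:
    """Ground-truth world from which accident records are drawn."""

    seed: int
    n_records: int
    p_is: dict[str, float]
    p_cs_given_is: dict[str, dict[str, float]]
    p_rc_given_is_cs: dict[tuple[str, str], dict[str, float]]
    speed_dists: dict[tuple[str, str, str], WeibullParams]
    cluster_map: dict[str, str]
    sources: tuple[str, ...] = ("SYN_A", "SYN_B")

    def __post_init__(self) -> None:
        for name, block in [("p_is", self.p_is)] + [
            (f"p_cs_given_is[{s}]", b) for s, b in self.p_cs_given_is.items()
        ]:
            if abs(sum(block.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} not normalized")


def default_world(seed: int = 0, n_records: int = 20_000) -> GeneratorConfig:
    """The default synthetic world: five conflict situations in three
    clusters, three severities; severe and fatal strata carry data for only
    two conflict situations, mirroring the sparsity of real in-depth
    databases."""
    cluster_map = {
        "SCPPL": "CrossingStraight", "SCPPR": "CrossingStraight",
        "SCPOL": "CrossingOblique", "SCPOR": "CrossingOblique",
        "TAPPL": "Turning",
    }
    p_cs = {
        "slight": {"SCPPL": 0.30, "SCPPR": 0.25, "SCPOL": 0.18, "SCPOR": 0.15, "TAPPL": 0.12},
        "severe": {"SCPPL": 0.55, "SCPPR": 0.45},
        "fatal": {"SCPPL": 0.60, "SCPPR": 0.40},
    }
    p_rc = {
        (sev, cs): {"dry": dry, "non_dry": 1.0 - dry}
        for sev, dry in (("slight", 0.80), ("severe", 0.75), ("fatal", 0.70))
        for cs in p_cs[sev]
    }
    veh = {"slight": (2.0, 32.0), "severe": (2.2, 48.0), "fatal": (2.4, 65.0)}
    vru = {"slight": (1.7, 5.0), "severe": (1.8, 5.5), "fatal": (1.9, 6.0)}
    cs_speed_factor = {"SCPPL": 1.0, "SCPPR": 0.95, "SCPOL": 1.05, "SCPOR": 0.9, "TAPPL": 0.85}
    speed_dists = {}
    for sev, block in p_cs.items():
        for cs in block:
            for subject, (shape, scale) in (("vehicle", veh[sev]), ("vru", vru[sev])):
                speed_dists[(sev, cs, subject)] = WeibullParams(
                    shape=shape, scale=scale * cs_speed_factor[cs], n=3,
                    stratum=(cs, sev), subject=subject,
                )
    return GeneratorConfig(
        seed=seed, n_records=n_records,
        p_is={"slight": 0.70, "severe": 0.25, "fatal": 0.05},
        p_cs_given_is=p_cs, p_rc_given_is_cs=p_rc,
        speed_dists=speed_dists, cluster_map=cluster_map,
    )


def generate_accidents(cfg: GeneratorConfig) -> list[AccidentRecord]:
    """Draw accident records from the configured world; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    severities = sorted(cfg.p_is)
    p_sev = np.array([cfg.p_is[s] for s in severities])
    records: list[AccidentRecord] = []
    for i in range(cfg.n_records):
        sev = severities[rng.choice(len(severities), p=p_sev)]
        cs_block = cfg.p_cs_given_is[sev]
        cs_names = sorted(cs_block)
        cs = cs_names[rng.choice(len(cs_names), p=np.array([cs_block[c] for c in cs_names]))]
        rc_block = cfg.p_rc_given_is_cs[(sev, cs)]
        rc_names = sorted(rc_block)
        rc = rc_names[rng.choice(len(rc_names), p=np.array([rc_block[r] for r in rc_names]))]
        speeds = {}
        for subject in ("vehicle", "vru"):
            d = cfg.speed_dists.get((sev, cs, subject))
            if d is None:
                raise KeyError(f"no speed distribution for stratum ({sev!r}, {cs!r}, {subject!r})")
            speeds[subject] = float(d.scale * rng.weibull(d.shape))
        records.append(
            AccidentRecord(
                case_id=f"SYN{i:06d}", conflict_situation=cs,
                cluster=cfg.cluster_map[cs], injury_severity=sev,
                v_veh0=speeds["vehicle"], v_vru0=speeds["vru"],
                road_condition=rc, source=cfg.sources[i % len(cfg.sources)],
            )
        )
    return records


# -- surrogate in-crash injury response ---------------------------------------

def _default_coefficients() -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """(intercept, slope vs v_veh km/h, slope vs |CP| %, slope vs angle
    deviation from 90 deg) per (criterion, anthropometry)."""
    base = {
        "skull": {"F50": -4.6, "M50": -4.0},
        "brain_ais1": {"F50": -1.8, "M50": -1.8},
        "brain_ais2": {"F50": -2.8, "M50": -2.8},
        "brain_ais3": {"F50": -3.8, "M50": -3.8},
        "brain_ais4": {"F50": -4.8, "M50": -4.8},
        "ribs_3plus": {"F50": -5.5, "M50": -4.0},
        "prox_femur_l": {"F50": -3.0, "M50": -4.0},
        "prox_femur_r": {"F50": -3.1, "M50": -4.1},
        "femur_shaft_l": {"F50": -4.2, "M50": -4.2},
        "femur_shaft_r": {"F50": -4.3, "M50": -4.3},
        "tibia_shaft_l": {"F50": -3.9, "M50": -3.9},
        "tibia_shaft_r": {"F50": -4.0, "M50": -4.0},
    }
    slope_v = {"skull": 0.09, "brain_ais1": 0.09, "brain_ais2": 0.09,
               "brain_ais3": 0.09, "brain_ais4": 0.09, "ribs_3plus": 0.08}
    out = {}
    for crit, by_anthro in base.items():
        bv = slope_v.get(crit, 0.075)
        for anthro, b0 in by_anthro.items():
            out[(crit, anthro)] = (b0, bv, -0.008, -0.004)
    return out


@dataclass
class SurrogateInjuryConfig:
    """Deterministic logistic injury response standing in for FE simulations."""

    coefficients: dict[tuple[str, str], tuple[float, float, float, float]] = field(
        default_factory=_default_coefficients
    )
    pulse_scale: float = 2.0  # peak head acceleration [g] per km/h of collision speed
    pulse_duration: float = 0.010  # [s]
    signal_rate: float = 10_000.0  # [Hz]
    noise_sigma: float = 0.0  # optional Gaussian noise on the logit
    seed: int = 0


def _angle_dev(angle_deg: float) -> float:
    """Absolute deviation of the collision angle from a 90 deg side impact."""
    return abs(((angle_deg - 90.0 + 180.0) % 360.0) - 180.0)


def surrogate_risks(
    representative: Sequence[float],
    anthropometry: str,
    cfg: SurrogateInjuryConfig | None = None,
    rng: np.random.Generator | None = None,
) -> InjuryRiskVector:
    """Evaluate the logistic injury response at one collision-scenario
    representative (v_veh km/h, v_vru km/h, angle deg, cp %)."""
    cfg = cfg or SurrogateInjuryConfig()
    if anthropometry not in ANTHROPOMETRIES:
        raise ValueError(f"unknown anthropometry {anthropometry!r}")
    v, _, angle, cp = (float(x) for x in representative)
    risks = {}
    for crit in CRITERIA:
        b0, bv, bcp, ba = cfg.coefficients[(crit, anthropometry)]
        logit = b0 + bv * v + bcp * abs(cp) + ba * _angle_dev(angle)
        if cfg.noise_sigma > 0:
            if rng is None:
                rng = np.random.default_rng(cfg.seed)
            logit += float(rng.normal(0.0, cfg.noise_sigma))
        risks[crit] = _expit(logit)
    return InjuryRiskVector(risks=risks, anthropometry=anthropometry)


@dataclass
class SurrogateSignals:
    """Signal-level stand-in for one in-crash simulation."""

    head_lin_acc: Channel  # resultant, [g]
    head_ang_acc: Channel  # 3-axis, [rad/s^2]
    rib_strains: dict[str, float]
    bone_strains: dict[str, float]  # MPS99 per instrumented long bone


def surrogate_signals(
    representative: Sequence[float],
    cfg: SurrogateInjuryConfig | None = None,
) -> SurrogateSignals:
    """Half-sine head pulses and strain scalars with amplitudes
    proportional to the vehicle collision speed."""
    cfg = cfg or SurrogateInjuryConfig()
    v = float(representative[0])
    dt = 1.0 / cfg.signal_rate
    n = int(round(cfg.pulse_duration / dt)) + 1
    t = np.arange(3 * n) * dt  # pulse plus trailing quiet interval
    pulse = np.zeros(t.size)
    pulse[:n] = np.sin(np.linspace(0.0, np.pi, n))
    amp_lin = cfg.pulse_scale * v  # [g]
    amp_ang = 60.0 * v  # [rad/s^2]
    lin = Channel(t=t, values=amp_lin * pulse, kind="linear_acc_g")
    ang = Channel(
        t=t,
        values=np.stack([amp_ang * pulse, 0.5 * amp_ang * pulse, 0.25 * amp_ang * pulse], axis=1),
        kind="angular_acc_rad_s2",
    )
    rib_strains = {f"rib_{i:02d}": 0.0004 * v * (1.0 + 0.05 * i) for i in range(1, 13)}
    bone_strains = {
        bone: 0.0005 * v * factor
        for bone, factor in (
            ("prox_femur_l", 1.0), ("prox_femur_r", 0.95),
            ("femur_shaft_l", 0.9), ("femur_shaft_r", 0.85),
            ("tibia_shaft_l", 1.05), ("tibia_shaft_r", 1.0),
        )
    }
    return SurrogateSignals(
        head_lin_acc=lin, head_ang_acc=ang,
        rib_strains=rib_strains, bone_strains=bone_strains,
    )
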