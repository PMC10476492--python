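"""Virtual-testing-scenario catalog generation.

Expands the fitted probability tables into the discrete catalog of
pre-crash boundary conditions.  Each scenario carries an occurrence
probability

    P(scenario) = P(IS) * P(CS|IS) * P(v_veh|IS,CS) * P(v_vru|IS,CS) * P(RC|IS,CS)

where the speed factors come from an equal-probability percentile grid of
the fitted Weibull distributions (5% steps for the vehicle, 10% for the
pedestrian by default).  The occurrence model assigns no distribution to
the collision point, so each scenario's probability is split uniformly over
the configured collision-point values; the catalog then still sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accident_stats import ProbabilityTables, WeibullParams


@dataclass(frozen=True)
class VirtualTestingScenario:
    """One pre-crash boundary-condition set with occurrence probability."""

    id: str
    conflict_situation: str
    injury_severity: str
    road_condition: str
    v_veh0: float  # initial vehicle speed [km/h]
    v_vru0: float  # initial pedestrian speed [km/h]
    collision_point_target: float  # % of vehicle front width, -50..+50
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 < self.probability <= 1.0):
            raise ValueError(f"probability must be in (0, 1], got {self.probability}")
        if not (-50.0 <= self.collision_point_target <= 50.0):
            raise ValueError("collision point outside [-50, 50] %")


@dataclass
class CatalogConfig:
    veh_percentile_step: float = 5.0  # % -> 20 vehicle-speed grid points
    vru_percentile_step: float = 10.0  # % -> 10 pedestrian-speed grid points
    collision_point_values: tuple[float, ...] = (-40.0, -20.0, 0.0, 20.0, 40.0)
    lead_time: float = 4.0  # s of pre-collision travel used to place the start state

    def __post_init__(self) -> None:
        for step in (self.veh_percentile_step, self.vru_percentile_step):
            _check_step(step)
        if not self.collision_point_values:
            raise ValueError("collision_point_values must be non-empty")
        if any(not -50.0 <= cp <= 50.0 for cp in self.collision_point_values):
            raise ValueError("collision points must lie within [-50, 50] %")


def _check_step(step_pct: float) -> None:
    if not (0.0 < step_pct <= 50.0):
        raise ValueError(f"percentile step must be in (0, 50], got {step_pct}")
    if abs(100.0 / step_pct - round(100.0 / step_pct)) > 1e-9:
        raise ValueError(f"100 must be divisible by the percentile step, got {step_pct}")


def speed_grid(dist: WeibullParams, step_pct: float) -> list[tuple[float, float]]:
    """Equal-probability speed grid of a fitted distribution.

    The CDF is split into ``100/step_pct`` intervals; each grid speed is the
    inverse CDF at the interval midpoint and carries probability
    ``step_pct/100``.
    """
    _check_step(step_pct)
    k = int(round(100.0 / step_pct))
    q = (np.arange(k) + 0.5) / k
    speeds = dist.ppf(q)
    p = step_pct / 100.0
    return [(float(s), p) for s in speeds]


def scenario_id(
    cs: str, sev: str, rc: str, v_veh: float, v_vru: float, cp: float
) -> str:
    """Deterministic, lexicographically sortable scenario identifier."""
    return f"{cs}_{sev}_{rc}_v{v_veh:05.1f}_p{v_vru:04.1f}_cp{int(round(cp)):+03d}"


def scenario_probability(
    tables: ProbabilityTables,
    severity: str,
    conflict_situation: str,
    road_condition: str,
    p_v_veh: float,
    p_v_vru: float,
    n_collision_points: int = 1,
) -> float:
    """Occurrence probability of one scenario: product of the five factors,
    split uniformly over the scenario's collision-point values."""
    try:
        p_is = tables.p_is[severity]
    except KeyError:
        raise KeyError(f"P(IS) missing for severity {severity!r}") from None
    try:
        p_cs = tables.p_cs_given_is[severity][conflict_situation]
    except KeyError:
        raise KeyError(
            f"P(CS|IS) missing for ({severity!r}, {conflict_situation!r})"
        ) from None
    try:
        p_rc = tables.p_rc_given_is_cs[(severity, conflict_situation)][road_condition]
    except KeyError:
        raise KeyError(
            f"P(RC|IS,CS) missing for ({severity!r}, {conflict_situation!r}, {road_condition!r})"
        ) from None
    return p_is * p_cs * p_v_veh * p_v_vru * p_rc / n_collision_points


def build_catalog(
    tables: ProbabilityTables, config: CatalogConfig | None = None
) -> list[VirtualTestingScenario]:
    """Cartesian expansion into the full scenario catalog.

    Iterates severity x conflict situation x vehicle-speed grid x
    pedestrian-speed grid x road condition x collision point, restricted to
    strata for which both speed distributions were fitted.  Ordering and
    IDs are deterministic, so two builds from identical tables are
    identical.
    """
    config = config or CatalogConfig()
    if not tables.speed_dists:
        raise ValueError("tables hold no fitted speed distributions")
    ncp = len(config.collision_point_values)
    scenarios: list[VirtualTestingScenario] = []
    strata = sorted(
        {
            (sev, cs)
            for (sev, cs, subj) in tables.speed_dists
            if (sev, cs, "vehicle") in tables.speed_dists
            and (sev, cs, "vru") in tables.speed_dists
        }
    )
    if not strata:
        raise ValueError("no stratum has both vehicle and pedestrian speed distributions")
    for sev, cs in strata:
        veh_grid = speed_grid(tables.speed_dists[(sev, cs, "vehicle")], config.veh_percentile_step)
        vru_grid = speed_grid(tables.speed_dists[(sev, cs, "vru")], config.vru_percentile_step)
        for rc in sorted(tables.p_rc_given_is_cs[(sev, cs)]):
            for v_veh, p_v in veh_grid:
                for v_vru, p_p in vru_grid:
                    for cp in config.collision_point_values:
                        prob = scenario_probability(tables, sev, cs, rc, p_v, p_p, ncp)
                        if prob <= 0.0:
                            continue
                        scenarios.append(
                            VirtualTestingScenario(
                                id=scenario_id(cs, sev, rc, v_veh, v_vru, cp),
                                conflict_situation=cs,
                                injury_severity=sev,
                                road_condition=rc,
                                v_veh0=v_veh,
                                v_vru0=v_vru,
                                collision_point_target=cp,
                                probability=prob,
                            )
                        )
    return scenarios


CATALOG_COLUMNS = [
    "id", "conflict_situation", "injury_severity", "road_condition",
    "v_veh0_kmh", "v_vru0_kmh", "collision_point_pct", "probability",
]

#: mapping from a commonly published catalog schema to the native one;
#: pass to :func:`read_catalog` when loading an external catalog.
RELEASED_CATALOG_COLUMN_MAP = {
    "IDs": "id",
    "Collision speed baseline": "v_veh0_kmh",
    "Collision speed VRU": "v_vru0_kmh",
    "Collision point baseline": "collision_point_pct",
}


def write_catalog(scenarios: Sequence[VirtualTestingScenario], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": s.id, "conflict_situation": s.conflict_situation,
                "injury_severity": s.injury_severity, "road_condition": s.road_condition,
                "v_veh0_kmh": s.v_veh0, "v_vru0_kmh": s.v_vru0,
                "collision_point_pct": s.collision_point_target, "probability": s.probability,
            }
            for s in scenarios
        ],
        columns=CATALOG_COLUMNS,
    ).to_csv(path, index=False)


def read_catalog(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = {"id", "v_veh0_kmh", "v_vru0_kmh"} - set(df.columns)
    if missing:
        raise ValueError(f"catalog file missing columns: {sorted(missing)}")
    return df
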