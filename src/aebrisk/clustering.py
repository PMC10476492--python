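"""Binning of collision outcomes into collision scenarios.

Collision quantities are binned on a fixed grid — vehicle collision speed
in 5 km/h intervals over 0-120, pedestrian collision speed in 1 km/h
intervals over 0-20, collision angle in 30 deg intervals over 0-360 and
collision point in 5% intervals over -50..+50.  Bins are left-closed /
right-open with the global upper endpoint closed.  The probability of a
collision scenario is the sum of the occurrence probabilities of the
(deterministically simulated) virtual testing scenarios that land in its
bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .precrash import CollisionOutcome

#: (lower bound, upper bound, bin width) per clustered quantity
BIN_SPECS = {
    "v_veh": (0.0, 120.0, 5.0),
    "v_vru": (0.0, 20.0, 1.0),
    "angle": (0.0, 360.0, 30.0),
    "cp": (-50.0, 50.0, 5.0),
}


@dataclass(frozen=True, order=True)
class ClusterKey:
    v_veh_bin: int
    v_vru_bin: int
    angle_bin: int
    cp_bin: int

    def __post_init__(self) -> None:
        for name, quantity in (
            ("v_veh_bin", "v_veh"), ("v_vru_bin", "v_vru"),
            ("angle_bin", "angle"), ("cp_bin", "cp"),
        ):
            lo, hi, width = BIN_SPECS[quantity]
            n_bins = int(round((hi - lo) / width))
            idx = getattr(self, name)
            if not 0 <= idx < n_bins:
                raise ValueError(f"{name}={idx} outside the {n_bins}-bin grid")

    @property
    def midpoints(self) -> tuple[float, float, float, float]:
        """Bin midpoints (v_veh km/h, v_vru km/h, angle deg, cp %)."""
        out = []
        for name, quantity in (
            ("v_veh_bin", "v_veh"), ("v_vru_bin", "v_vru"),
            ("angle_bin", "angle"), ("cp_bin", "cp"),
        ):
            lo, _, width = BIN_SPECS[quantity]
            out.append(lo + (getattr(self, name) + 0.5) * width)
        return tuple(out)


@dataclass
class CollisionScenario:
    """One occupied bin: representative point, probability and members."""

    key: ClusterKey
    representative: tuple[float, float, float, float]
    probability: float
    member_ids: list[str]


def _bin_index(value: float, quantity: str) -> int:
    lo, hi, width = BIN_SPECS[quantity]
    if not lo <= value <= hi:
        raise ValueError(f"{quantity} value {value} outside range [{lo}, {hi}]")
    n_bins = int(round((hi - lo) / width))
    idx = int(np.floor((value - lo) / width))
    return min(idx, n_bins - 1)  # upper range endpoint joins the last bin


def assign(outcome: CollisionOutcome) -> ClusterKey:
    """Bin one collided outcome; raises on avoided outcomes or
    out-of-range values, naming the offending quantity."""
    if not outcome.collided:
        raise ValueError("cannot assign an avoided outcome to a collision bin")
    angle = outcome.angle % 360.0
    return ClusterKey(
        v_veh_bin=_bin_index(outcome.v_veh_coll, "v_veh"),
        v_vru_bin=_bin_index(outcome.v_vru_coll, "v_vru"),
        angle_bin=_bin_index(angle, "angle"),
        cp_bin=_bin_index(outcome.collision_point, "cp"),
    )


def aggregate(
    outcomes: Sequence[CollisionOutcome],
    scenario_probabilities: Mapping[str, float],
) -> list[CollisionScenario]:
    """Aggregate deterministic outcomes into the collision-scenario table.

    Since the pre-crash simulation is deterministic, the conditional
    probability of a bin given a virtual testing scenario is a 0/1
    indicator, so each bin's probability is the plain sum of its members'
    occurrence probabilities.  Avoided outcomes contribute nothing.
    """
    seen: set[str] = set()
    table: dict[ClusterKey, CollisionScenario] = {}
    for o in outcomes:
        if o.scenario_id in seen:
            raise ValueError(f"duplicate scenario id {o.scenario_id!r}")
        seen.add(o.scenario_id)
        if not o.collided:
            continue
        if o.scenario_id not in scenario_probabilities:
            raise ValueError(f"no occurrence probability for scenario {o.scenario_id!r}")
        key = assign(o)
        entry = table.get(key)
        if entry is None:
            table[key] = CollisionScenario(
                key=key, representative=key.midpoints,
                probability=scenario_probabilities[o.scenario_id],
                member_ids=[o.scenario_id],
            )
        else:
            entry.probability += scenario_probabilities[o.scenario_id]
            entry.member_ids.append(o.scenario_id)
    return [table[k] for k in sorted(table)]


CLUSTER_COLUMNS = ["v_veh_mid", "v_vru_mid", "angle_mid", "cp_mid", "probability", "n_members"]


def clusters_to_frame(clusters: Sequence[CollisionScenario]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "v_veh_mid": c.representative[0], "v_vru_mid": c.representative[1],
                "angle_mid": c.representative[2], "cp_mid": c.representative[3],
                "probability": c.probability, "n_members": len(c.member_ids),
            }
            for c in clusters
        ],
        columns=CLUSTER_COLUMNS,
    )


def write_clusters(clusters: Sequence[CollisionScenario], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, index=False)


def read_clusters(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
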