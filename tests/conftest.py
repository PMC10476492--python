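import numpy as np
import pytest

from aebrisk.accident_stats import ProbabilityTables, WeibullParams
from aebrisk.catalog import CatalogConfig, VirtualTestingScenario, build_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tables() -> ProbabilityTables:
    """A complete two-stratum probability world, exact by construction."""
    dists = {}
    for sev, cs, scale_v in (("slight", "SCPPL", 30.0), ("severe", "SCPPR", 45.0)):
        dists[(sev, cs, "vehicle")] = WeibullParams(2.0, scale_v, 100, (cs, sev), "vehicle")
        dists[(sev, cs, "vru")] = WeibullParams(1.8, 5.0, 100, (cs, sev), "vru")
    return ProbabilityTables(
        p_is={"slight": 0.7, "severe": 0.3},
        p_cs_given_is={"slight": {"SCPPL": 1.0}, "severe": {"SCPPR": 1.0}},
        p_rc_given_is_cs={
            ("slight", "SCPPL"): {"dry": 0.8, "non_dry": 0.2},
            ("severe", "SCPPR"): {"dry": 0.75, "non_dry": 0.25},
        },
        speed_dists=dists,
    )


@pytest.fixture
def small_catalog(small_tables) -> list[VirtualTestingScenario]:
    cfg = CatalogConfig(
        veh_percentile_step=25.0, vru_percentile_step=50.0,
        collision_point_values=(-20.0, 0.0, 20.0),
    )
    return build_catalog(small_tables, cfg)


def crossing_scenario(
    v_veh: float = 30.0, v_vru: float = 3.6, cp: float = 0.0,
    rc: str = "dry", cs: str = "SCPPL", prob: float = 1.0,
) -> VirtualTestingScenario:
    return VirtualTestingScenario(
        id=f"test_{cs}_{v_veh}_{v_vru}_{cp}_{rc}", conflict_situation=cs,
        injury_severity="slight", road_condition=rc,
        v_veh0=v_veh, v_vru0=v_vru, collision_point_target=cp, probability=prob,
    )
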