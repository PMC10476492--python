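"""Workflow orchestration: the six assessment steps as composable stages.

Stages (each writes delimited-text artifacts into the run directory and
embeds the hash of the resolved configuration so downstream stages can
detect mismatched inputs):

1. ``fit-stats``      — generate/load accident records, fit probability tables
2. ``build-catalog``  — expand tables into the virtual-testing-scenario catalog
3. ``simulate``       — baseline and AEB pre-crash simulation of the catalog
4. ``cluster``        — bin collision outcomes into collision scenarios
5. ``select-doe``     — MaxPro selection of the in-crash simulation matrix
6. ``evaluate-injury``— surrogate injury risks for every collision scenario
7. ``fit-metamodel``  — train-size sweep of the Gaussian-process surrogate
8. ``report``         — crash-risk reduction, speed histograms, overall risks
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, doe, injury, metamodel, precrash, synthetic
from .accident_stats import ProbabilityTables, fit_tables, read_accident_records, write_accident_records
from .catalog import CatalogConfig, VirtualTestingScenario, build_catalog, read_catalog, write_catalog
from .clustering import CollisionScenario, aggregate, clusters_to_frame
from .doe import select, write_design
from .injury import ANTHROPOMETRIES, CRITERIA, overall_risk
from .metamodel import SurrogateConfig, train_size_sweep
from .precrash import AEBConfig, VehicleGeometry, crash_risk_reduction, simulate_catalog, write_outcomes
from .synthetic import SurrogateInjuryConfig, default_world, generate_accidents, surrogate_risks

log = logging.getLogger("aebrisk")

STEPS = (
    "fit-stats", "build-catalog", "simulate", "cluster",
    "select-doe", "evaluate-injury", "fit-metamodel", "report", "all",
)

#: which step produces which artifact (for dependency error messages)
PRODUCERS = {
    "records.csv": "fit-stats",
    "tables.yaml": "fit-stats",
    "catalog.csv": "build-catalog",
    "outcomes.csv": "simulate",
    "clusters_baseline.csv": "cluster",
    "clusters_aeb.csv": "cluster",
    "doe.csv": "select-doe",
    "risks_baseline.csv": "evaluate-injury",
    "risks_aeb.csv": "evaluate-injury",
    "metamodel_sweep.csv": "fit-metamodel",
    "report.json": "report",
}


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    n_records: int = 20_000
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    aeb: AEBConfig = field(default_factory=AEBConfig)
    geometry: VehicleGeometry = field(default_factory=VehicleGeometry)
    surrogate: SurrogateConfig = field(
        default_factory=lambda: SurrogateConfig(optimizer_restarts=5)
    )
    injury_response: SurrogateInjuryConfig = field(default_factory=SurrogateInjuryConfig)
    doe_n_total: int = 50
    doe_high_fraction: float = 0.6
    doe_high_quantile: float = 0.5
    verification_n_cases: int = 200
    sweep_sizes: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 80, 100)
    records_path: str | None = None  # external accident records; synthetic when None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["injury_response"]["coefficients"] = {
            f"{crit}|{anthro}": list(v)
            for (crit, anthro), v in self.injury_response.coefficients.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        inj = dict(d.pop("injury_response", {}))
        if "coefficients" in inj:
            inj["coefficients"] = {
                tuple(k.split("|")): tuple(v) for k, v in inj["coefficients"].items()
            }
        cat = dict(d.pop("catalog", {}))
        if "collision_point_values" in cat:
            cat["collision_point_values"] = tuple(cat["collision_point_values"])
        return cls(
            catalog=CatalogConfig(**cat),
            aeb=AEBConfig(**d.pop("aeb", {})),
            geometry=VehicleGeometry(**d.pop("geometry", {})),
            surrogate=SurrogateConfig(**d.pop("surrogate", {})),
            injury_response=SurrogateInjuryConfig(**inj),
            sweep_sizes=tuple(d.pop("sweep_sizes", (10, 20, 30, 40, 50, 60, 80, 100))),
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


class MissingArtifactError(FileNotFoundError):
    pass


class ConfigHashMismatch(RuntimeError):
    pass


class Pipeline:
    """Executes pipeline stages against one run directory."""

    def __init__(self, cfg: RunConfig, outdir: str | Path, allow_hash_mismatch: bool = False):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.allow_hash_mismatch = allow_hash_mismatch
        self.hash = cfg.config_hash

    # -- artifact plumbing ---------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, name: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise MissingArtifactError(
                f"missing artifact {name!r}; run step {PRODUCERS[name]!r} first"
            )
        self._check_hash(p)
        return p

    def _check_hash(self, path: Path) -> None:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
        if first.startswith("# config_hash="):
            found = first.split("=", 1)[1]
            if found != self.hash and not self.allow_hash_mismatch:
                raise ConfigHashMismatch(
                    f"{path.name} was produced with config {found}, current is {self.hash}"
                )

    def _write_frame(self, df: pd.DataFrame, name: str) -> None:
        p = self._path(name)
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(f"# config_hash={self.hash}\n")
            df.to_csv(fh, index=False)
        log.info("wrote %s (%d rows, config %s)", p, len(df), self.hash)

    def _read_frame(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self._require(name), comment="#")

    # -- stages ----------------------------------------------------------------

    def fit_stats(self) -> ProbabilityTables:
        if self.cfg.records_path:
            records = read_accident_records(self.cfg.records_path)
        else:
            world = default_world(seed=self.cfg.seed, n_records=self.cfg.n_records)
            records = generate_accidents(world)
        write_accident_records(records, self._path("records.csv"))
        tables = fit_tables(records)
        with open(self._path("tables.yaml"), "w", encoding="utf-8") as fh:
            fh.write(f"# config_hash={self.hash}\n")
            fh.write(yaml.safe_dump(tables.to_dict(), sort_keys=True))
        log.info("fitted tables: %d strata with speed distributions", len(tables.speed_dists))
        return tables

    def _load_tables(self) -> ProbabilityTables:
        path = self._require("tables.yaml")
        return ProbabilityTables.from_dict(yaml.safe_load(path.read_text(encoding="utf-8")))

    def build_catalog(self) -> list[VirtualTestingScenario]:
        tables = self._load_tables()
        scenarios = build_catalog(tables, self.cfg.catalog)
        df = pd.DataFrame(
            [
                {
                    "id": s.id, "conflict_situation": s.conflict_situation,
                    "injury_severity": s.injury_severity, "road_condition": s.road_condition,
                    "v_veh0_kmh": s.v_veh0, "v_vru0_kmh": s.v_vru0,
                    "collision_point_pct": s.collision_point_target, "probability": s.probability,
                }
                for s in scenarios
            ]
        )
        self._write_frame(df, "catalog.csv")
        return scenarios

    def _load_scenarios(self) -> list[VirtualTestingScenario]:
        df = self._read_frame("catalog.csv")
        return [
            VirtualTestingScenario(
                id=r.id, conflict_situation=r.conflict_situation,
                injury_severity=r.injury_severity, road_condition=r.road_condition,
                v_veh0=r.v_veh0_kmh, v_vru0=r.v_vru0_kmh,
                collision_point_target=r.collision_point_pct, probability=r.probability,
            )
            for r in df.itertuples(index=False)
        ]

    def simulate(self):
        scenarios = self._load_scenarios()
        lead = self.cfg.catalog.lead_time
        baseline = simulate_catalog(
            scenarios, geom=self.cfg.geometry, aeb=None, lead_time=lead
        )
        with_aeb = simulate_catalog(
            scenarios, geom=self.cfg.geometry, aeb=self.cfg.aeb, lead_time=lead
        )
        aeb_by_id = {o.scenario_id: o for o in with_aeb}
        rows = []
        for b in baseline:
            a = aeb_by_id[b.scenario_id]
            rows.append(
                {
                    "id": b.scenario_id,
                    "v_veh_coll_baseline_kmh": b.v_veh_coll,
                    "cp_baseline_pct": b.collision_point,
                    "angle_baseline_deg": b.angle,
                    "v_vru_coll_kmh": b.v_vru_coll,
                    "v_veh_coll_aeb_kmh": a.v_veh_coll if a.collided else None,
                    "cp_aeb_pct": a.collision_point if a.collided else None,
                    "angle_aeb_deg": a.angle if a.collided else None,
                }
            )
        self._write_frame(pd.DataFrame(rows, columns=precrash.OUTCOME_COLUMNS), "outcomes.csv")
        log.info(
            "simulated %d scenarios: %d avoided with AEB",
            len(scenarios), sum(1 for o in with_aeb if not o.collided),
        )
        return scenarios, baseline, with_aeb

    def _outcomes_from_table(self):
        df = self._read_frame("outcomes.csv")
        baseline, with_aeb = [], []
        for r in df.itertuples(index=False):
            baseline.append(
                precrash.CollisionOutcome(
                    scenario_id=r.id, collided=True,
                    v_veh_coll=r.v_veh_coll_baseline_kmh, v_vru_coll=r.v_vru_coll_kmh,
                    angle=r.angle_baseline_deg, collision_point=r.cp_baseline_pct,
                )
            )
            if pd.isna(r.v_veh_coll_aeb_kmh):
                with_aeb.append(precrash.CollisionOutcome(scenario_id=r.id, collided=False))
            else:
                with_aeb.append(
                    precrash.CollisionOutcome(
                        scenario_id=r.id, collided=True,
                        v_veh_coll=r.v_veh_coll_aeb_kmh, v_vru_coll=r.v_vru_coll_kmh,
                        angle=r.angle_aeb_deg, collision_point=r.cp_aeb_pct,
                        aeb_triggered=True,
                    )
                )
        return baseline, with_aeb

    def cluster(self):
        scenarios = self._load_scenarios()
        probs = {s.id: s.probability for s in scenarios}
        baseline, with_aeb = self._outcomes_from_table()
        clusters_baseline = aggregate(baseline, probs)
        clusters_aeb = aggregate(with_aeb, probs)
        self._write_frame(clusters_to_frame(clusters_baseline), "clusters_baseline.csv")
        self._write_frame(clusters_to_frame(clusters_aeb), "clusters_aeb.csv")
        log.info(
            "clustered: %d baseline / %d AEB collision scenarios",
            len(clusters_baseline), len(clusters_aeb),
        )
        return clusters_baseline, clusters_aeb

    def _load_clusters(self, name: str) -> list[CollisionScenario]:
        df = self._read_frame(name)
        out = []
        for r in df.itertuples(index=False):
            key = clustering.ClusterKey(
                v_veh_bin=int(round((r.v_veh_mid - 2.5) / 5.0)),
                v_vru_bin=int(round(r.v_vru_mid - 0.5)),
                angle_bin=int(round((r.angle_mid - 15.0) / 30.0)),
                cp_bin=int(round((r.cp_mid + 50.0 - 2.5) / 5.0)),
            )
            out.append(
                CollisionScenario(
                    key=key,
                    representative=(r.v_veh_mid, r.v_vru_mid, r.angle_mid, r.cp_mid),
                    probability=r.probability, member_ids=[],
                )
            )
        return out

    def select_doe(self):
        clusters = self._load_clusters("clusters_baseline.csv")
        design = select(
            clusters, n_total=min(self.cfg.doe_n_total, len(clusters)),
            high_fraction=self.cfg.doe_high_fraction,
            high_quantile=self.cfg.doe_high_quantile,
        )
        rows = []
        for order, idx in enumerate(design.selected):
            c = clusters[idx]
            rows.append(
                {
                    "selection_order": order, "candidate_index": idx,
                    "v_veh_mid": c.representative[0], "v_vru_mid": c.representative[1],
                    "angle_mid": c.representative[2], "cp_mid": c.representative[3],
                    "probability": c.probability,
                }
            )
        self._write_frame(pd.DataFrame(rows, columns=doe.DOE_COLUMNS), "doe.csv")
        return design, clusters

    def evaluate_injury(self):
        """Ground-truth surrogate risks for every collision scenario."""
        for name, out_name in (
            ("clusters_baseline.csv", "risks_baseline.csv"),
            ("clusters_aeb.csv", "risks_aeb.csv"),
        ):
            clusters = self._load_clusters(name)
            rows = []
            for c in clusters:
                for anthro in ANTHROPOMETRIES:
                    vec = surrogate_risks(c.representative, anthro, self.cfg.injury_response)
                    row = {
                        "v_veh_mid": c.representative[0], "v_vru_mid": c.representative[1],
                        "angle_mid": c.representative[2], "cp_mid": c.representative[3],
                        "probability": c.probability, "anthropometry": anthro,
                    }
                    row.update(vec.risks)
                    rows.append(row)
            self._write_frame(pd.DataFrame(rows), out_name)

    def fit_metamodel(self) -> pd.DataFrame:
        """Train-size sweep on MaxPro-ordered baseline cases (F50)."""
        clusters = self._load_clusters("clusters_baseline.csv")
        n_cases = min(self.cfg.verification_n_cases, len(clusters))
        design = select(
            clusters, n_total=n_cases,
            high_fraction=self.cfg.doe_high_fraction,
            high_quantile=self.cfg.doe_high_quantile,
        )
        X = np.array([clusters[i].representative for i in design.selected])
        probs = np.array([clusters[i].probability for i in design.selected])
        risks = {
            crit: np.array(
                [
                    surrogate_risks(clusters[i].representative, "F50", self.cfg.injury_response).risks[crit]
                    for i in design.selected
                ]
            )
            for crit in CRITERIA
        }
        sizes = [s for s in self.cfg.sweep_sizes if s <= n_cases]
        sweep = train_size_sweep(
            X, risks, probs, cfg=self.cfg.surrogate, sizes=sizes
        )
        self._write_frame(sweep, "metamodel_sweep.csv")
        return sweep

    def report(self) -> dict:
        scenarios = self._load_scenarios()
        probs = {s.id: s.probability for s in scenarios}
        baseline, with_aeb = self._outcomes_from_table()
        reduction = crash_risk_reduction(scenarios, with_aeb)

        def mean_speeds(outcomes):
            collided = [o for o in outcomes if o.collided]
            v = np.array([o.v_veh_coll for o in collided])
            w = np.array([probs[o.scenario_id] for o in collided])
            return {
                "weighted_kmh": float((v * w).sum() / w.sum()) if w.sum() else float("nan"),
                "unweighted_kmh": float(v.mean()) if v.size else float("nan"),
                "n_collided": len(collided),
            }

        # residual-speed histogram, 5 km/h bins (baseline vs AEB probabilities)
        edges = np.arange(0.0, 125.0, 5.0)
        hist_rows = []
        for label, outcomes in (("baseline", baseline), ("aeb", with_aeb)):
            collided = [o for o in outcomes if o.collided]
            v = np.array([o.v_veh_coll for o in collided])
            w = np.array([probs[o.scenario_id] for o in collided])
            h, _ = np.histogram(v, bins=edges, weights=w)
            for lo, p in zip(edges[:-1], h):
                hist_rows.append({"condition": label, "v_low_kmh": lo, "probability": float(p)})
        self._write_frame(pd.DataFrame(hist_rows), "speed_histogram.csv")

        # per-criterion overall risks from the ground-truth risk tables
        risk_table = {}
        colliding_mass = {}
        for cond, name in (("baseline", "risks_baseline.csv"), ("aeb", "risks_aeb.csv")):
            df = self._read_frame(name)
            colliding_mass[cond] = float(
                df[df.anthropometry == ANTHROPOMETRIES[0]].probability.sum()
            )
            for anthro in ANTHROPOMETRIES:
                sub = df[df.anthropometry == anthro]
                for crit in CRITERIA:
                    norm = overall_risk(sub.probability.to_numpy(), sub[crit].to_numpy())
                    risk_table[f"{cond}.{anthro}.{crit}"] = {
                        "normalized": norm,
                        "absolute": norm * colliding_mass[cond],
                    }

        report = {
            "config_hash": self.hash,
            "seed": self.cfg.seed,
            "n_scenarios": len(scenarios),
            "n_clusters_baseline": int(len(self._read_frame("clusters_baseline.csv"))),
            "n_clusters_aeb": int(len(self._read_frame("clusters_aeb.csv"))),
            "n_avoided": sum(1 for o in with_aeb if not o.collided),
            "n_unavoidable": sum(1 for o in with_aeb if o.collided),
            "crash_risk_reduction_pct": reduction,
            "mean_collision_speed_baseline": mean_speeds(baseline),
            "mean_collision_speed_aeb": mean_speeds(with_aeb),
            "colliding_probability_mass": colliding_mass,
            "overall_risks": risk_table,
        }
        with open(self._path("report.json"), "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("report: crash risk reduction %.2f%%", reduction)
        return report

    def run(self, step: str = "all"):
        if step not in STEPS:
            raise ValueError(f"unknown step {step!r}; choose from {STEPS}")
        self.cfg.to_yaml(self._path("run_config.yaml"))
        dispatch = {
            "fit-stats": self.fit_stats,
            "build-catalog": self.build_catalog,
            "simulate": self.simulate,
            "cluster": self.cluster,
            "select-doe": self.select_doe,
            "evaluate-injury": self.evaluate_injury,
            "fit-metamodel": self.fit_metamodel,
            "report": self.report,
        }
        if step == "all":
            result = None
            for name in (
                "fit-stats", "build-catalog", "simulate", "cluster",
                "select-doe", "evaluate-injury", "fit-metamodel", "report",
            ):
                log.info("step %s (config %s)", name, self.hash)
                result = dispatch[name]()
            return result
        return dispatch[step]()
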