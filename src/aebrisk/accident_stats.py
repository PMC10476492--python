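"""Accident-statistics estimation.

Builds the probability building blocks of the scenario occurrence model
from reconstructed accident records:

* per-stratum Weibull distributions of the initial vehicle and pedestrian
  speeds (one stratum = one conflict situation x injury severity),
* injury-severity probabilities P(IS),
* conflict-situation probabilities P(CS|IS), estimated within clusters of
  conflict situations via iterative proportional fitting (IPF) across
  source databases and then weighted by base-level cluster shares,
* road-condition probabilities P(RC|IS,CS).

All tables serialize to a YAML config consumed by :mod:`aebrisk.catalog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

SEVERITIES = ("slight", "severe", "fatal")
ROAD_CONDITIONS = ("dry", "non_dry")
SUBJECTS = ("vehicle", "vru")

#: cluster labels dropped before share normalization: they do not describe a
#: simulatable motion pattern and therefore cannot seed a testing scenario.
EXCLUDED_CLUSTERS = frozenset({"Unspecified", "Others"})


class InsufficientDataError(ValueError):
    """Raised when a stratum holds fewer speed samples than required."""


@dataclass(frozen=True)
class AccidentRecord:
    """One reconstructed car-pedestrian case."""

    case_id: str
    conflict_situation: str
    cluster: str
    injury_severity: str
    v_veh0: float  # initial vehicle speed [km/h]
    v_vru0: float  # initial pedestrian speed [km/h]
    road_condition: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.injury_severity not in SEVERITIES:
            raise ValueError(f"unknown injury severity {self.injury_severity!r}")
        if self.road_condition not in ROAD_CONDITIONS:
            raise ValueError(f"unknown road condition {self.road_condition!r}")
        for name in ("v_veh0", "v_vru0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass(frozen=True)
class WeibullParams:
    """Maximum-likelihood Weibull parameters of an initial-speed distribution."""

    shape: float
    scale: float  # [km/h]
    n: int
    stratum: tuple[str, str] | None = None  # (conflict_situation, injury_severity)
    subject: str | None = None  # "vehicle" | "vru"

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")
        if self.n < 3:
            raise ValueError("n must be at least 3")

    def cdf(self, x) -> np.ndarray:
        return stats.weibull_min.cdf(x, self.shape, scale=self.scale)

    def ppf(self, q) -> np.ndarray:
        return stats.weibull_min.ppf(q, self.shape, scale=self.scale)

    def ks_statistic(self, samples: Sequence[float]) -> float:
        """Kolmogorov-Smirnov distance of samples to the fitted CDF.

        Informational only: the fit is never rejected on its basis, but the
        value is useful when judging sparse strata.
        """
        return float(stats.kstest(samples, self.cdf).statistic)


def fit_weibull(
    samples: Sequence[float],
    min_n: int = 3,
    stratum: tuple[str, str] | None = None,
    subject: str | None = None,
) -> WeibullParams:
    """Fit a two-parameter Weibull distribution to speed samples by MLE.

    Zero speeds are excluded before fitting (the Weibull support is the
    positive half-line; a stationary pedestrian is represented by the lowest
    percentile of the speed grid instead).  The shape parameter solves the
    profile likelihood equation

        sum(x^k ln x)/sum(x^k) - 1/k = mean(ln x)

    by bracketed root finding; the scale then follows in closed form as
    ``(mean(x^k))**(1/k)``.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_n`` positive samples are available.
    """
    x = np.asarray(samples, dtype=float)
    if x.size and (not np.all(np.isfinite(x)) or np.any(x < 0)):
        raise ValueError("speed samples must be finite and non-negative")
    x = x[x > 0]
    if x.size < min_n:
        raise InsufficientDataError(
            f"insufficient stratum data: {x.size} positive samples, need {min_n}"
        )
    logx = np.log(x)
    mean_logx = logx.mean()

    def profile(k: float) -> float:
        # log-sum-exp for numerical stability at large shapes
        w = k * logx
        w -= w.max()
        ew = np.exp(w)
        return float((ew * logx).sum() / ew.sum() - 1.0 / k - mean_logx)

    lo, hi = 1e-3, 1.0
    while profile(hi) < 0 and hi < 1e4:
        hi *= 2.0
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all speeds identical")
    shape = optimize.brentq(profile, lo, hi, xtol=1e-10, rtol=1e-12, maxiter=200)
    scale = float(np.exp(mean_logx) * (np.exp(shape * (logx - mean_logx)).mean()) ** (1.0 / shape))
    return WeibullParams(shape=float(shape), scale=scale, n=int(x.size), stratum=stratum, subject=subject)


@dataclass
class ContingencyTable:
    """Counts (or weights) indexed by source database x conflict situation."""

    cells: np.ndarray  # shape (n_rows, n_cols), non-negative
    row_margins: np.ndarray
    col_margins: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        self.row_margins = np.asarray(self.row_margins, dtype=float)
        self.col_margins = np.asarray(self.col_margins, dtype=float)
        if np.any(self.cells < 0) or np.any(self.row_margins < 0) or np.any(self.col_margins < 0):
            raise ValueError("cells and margins must be non-negative")
        if abs(self.row_margins.sum() - self.col_margins.sum()) > 1e-9 * max(1.0, self.row_margins.sum()):
            raise ValueError("row and column margins must share the same total")


class IPFConvergenceError(RuntimeError):
    pass


def ipf(seed: ContingencyTable, tol: float = 1e-8, max_iter: int = 10_000) -> ContingencyTable:
    """Iterative proportional fitting of a seed table to target margins.

    Alternates proportional row and column scaling until both margin sets
    are matched within ``tol`` (maximum absolute deviation).  Zero seed
    cells stay zero, so the fitted table preserves the seed's cross-product
    (odds) ratios wherever they are defined.
    """
    cells = seed.cells.copy()
    rt, ct = seed.row_margins, seed.col_margins
    # structural feasibility: an all-zero row/column cannot carry positive mass
    if np.any((cells.sum(axis=1) == 0) & (rt > 0)):
        raise ValueError("infeasible margins: zero seed row with positive row target")
    if np.any((cells.sum(axis=0) == 0) & (ct > 0)):
        raise ValueError("infeasible margins: zero seed column with positive column target")
    for _ in range(max_iter):
        rs = cells.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cells *= np.where(rs > 0, rt / np.where(rs > 0, rs, 1.0), 0.0)[:, None]
        cs = cells.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cells *= np.where(cs > 0, ct / np.where(cs > 0, cs, 1.0), 0.0)[None, :]
        row_err = np.abs(cells.sum(axis=1) - rt).max()
        col_err = np.abs(cells.sum(axis=0) - ct).max()
        if max(row_err, col_err) <= tol:
            return ContingencyTable(
                cells=cells, row_margins=rt, col_margins=ct,
                row_labels=seed.row_labels, col_labels=seed.col_labels,
            )
    raise IPFConvergenceError(
        f"IPF did not converge in {max_iter} iterations; "
        f"worst margin violation {max(row_err, col_err):.3e} (row {row_err:.3e}, col {col_err:.3e})"
    )


def severity_probabilities(counts: Mapping[str, float]) -> dict[str, float]:
    """Normalize per-severity counts or weights to probabilities P(IS)."""
    if any(v < 0 for v in counts.values()):
        raise ValueError("severity counts must be non-negative")
    total = float(sum(counts.values()))
    if total == 0:
        raise ValueError("all-zero severity counts")
    return {k: float(v) / total for k, v in counts.items()}


def normalize_cluster_shares(shares: Mapping[str, float]) -> dict[str, float]:
    """Drop non-simulatable clusters and renormalize the remaining shares."""
    kept = {k: float(v) for k, v in shares.items() if k not in EXCLUDED_CLUSTERS}
    total = sum(kept.values())
    if total <= 0:
        raise ValueError("no probability mass left after excluding clusters")
    return {k: v / total for k, v in kept.items()}


def conflict_probabilities(
    within_cluster: Mapping[tuple[str, str], Mapping[str, float]],
    cluster_shares: Mapping[str, Mapping[str, float]],
) -> dict[tuple[str, str], float]:
    """Combine within-cluster conflict-situation distributions with cluster shares.

    Parameters
    ----------
    within_cluster
        ``(severity, cluster) -> {conflict_situation: probability}``; each
        block must sum to 1.
    cluster_shares
        ``severity -> {cluster: share}``; shares must sum to 1 per severity
        (after exclusion of the non-simulatable clusters).

    Returns
    -------
    ``(severity, conflict_situation) -> P(CS|IS)``, summing to 1 per severity.
    """
    out: dict[tuple[str, str], float] = {}
    for severity, shares in cluster_shares.items():
        ssum = sum(shares.values())
        if abs(ssum - 1.0) > 1e-9:
            raise ValueError(f"cluster shares for severity {severity!r} sum to {ssum}, not 1")
        for cluster, share in shares.items():
            block = within_cluster.get((severity, cluster))
            if block is None:
                raise ValueError(f"no within-cluster distribution for ({severity!r}, {cluster!r})")
            bsum = sum(block.values())
            if abs(bsum - 1.0) > 1e-9:
                raise ValueError(
                    f"within-cluster probabilities for ({severity!r}, {cluster!r}) sum to {bsum}"
                )
            for cs, p in block.items():
                out[(severity, cs)] = out.get((severity, cs), 0.0) + share * p
    return out


@dataclass
class ProbabilityTables:
    """All probability factors of the scenario occurrence model.

    ``p_is[sev]`` is P(IS); ``p_cs_given_is[sev][cs]`` is P(CS|IS);
    ``p_rc_given_is_cs[(sev, cs)][rc]`` is P(RC|IS,CS); ``speed_dists[(sev,
    cs, subject)]`` holds the fitted Weibull speed distribution.
    """

    p_is: dict[str, float]
    p_cs_given_is: dict[str, dict[str, float]]
    p_rc_given_is_cs: dict[tuple[str, str], dict[str, float]]
    speed_dists: dict[tuple[str, str, str], WeibullParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, block in [("p_is", self.p_is)] + [
            (f"p_cs_given_is[{s}]", b) for s, b in self.p_cs_given_is.items()
        ] + [(f"p_rc_given_is_cs[{k}]", b) for k, b in self.p_rc_given_is_cs.items()]:
            vals = list(block.values())
            if any(not (0.0 <= v <= 1.0 + 1e-12) for v in vals):
                raise ValueError(f"{name} holds a probability outside [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {sum(vals)}, not 1")

    # -- serialization (round-trip is bit-identical: keys sorted, floats repr'd)

    def to_dict(self) -> dict:
        return {
            "p_is": {k: float(v) for k, v in sorted(self.p_is.items())},
            "p_cs_given_is": {
                s: {cs: float(p) for cs, p in sorted(b.items())}
                for s, b in sorted(self.p_cs_given_is.items())
            },
            "p_rc_given_is_cs": {
                s: {cs: {rc: float(p) for rc, p in sorted(b.items())}
                    for (s2, cs), b in sorted(self.p_rc_given_is_cs.items()) if s2 == s}
                for s in sorted({k[0] for k in self.p_rc_given_is_cs})
            },
            "speed_dists": {
                s: {cs: {subj: {"shape": d.shape, "scale": d.scale, "n": d.n}
                         for (s2, cs2, subj), d in sorted(self.speed_dists.items())
                         if s2 == s and cs2 == cs}
                    for cs in sorted({k[1] for k in self.speed_dists if k[0] == s})}
                for s in sorted({k[0] for k in self.speed_dists})
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProbabilityTables":
        speed_dists = {
            (s, cs, subj): WeibullParams(
                shape=v["shape"], scale=v["scale"], n=v["n"], stratum=(cs, s), subject=subj
            )
            for s, by_cs in d.get("speed_dists", {}).items()
            for cs, by_subj in by_cs.items()
            for subj, v in by_subj.items()
        }
        return cls(
            p_is=dict(d["p_is"]),
            p_cs_given_is={s: dict(b) for s, b in d["p_cs_given_is"].items()},
            p_rc_given_is_cs={
                (s, cs): dict(b)
                for s, by_cs in d["p_rc_given_is_cs"].items()
                for cs, b in by_cs.items()
            },
            speed_dists=speed_dists,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProbabilityTables":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


# -- record I/O ---------------------------------------------------------------

RECORD_COLUMNS = [
    "case_id", "conflict_situation", "cluster", "injury_severity",
    "v_veh0_kmh", "v_vru0_kmh", "road_condition", "source",
]


def write_accident_records(records: Iterable[AccidentRecord], path: str | Path) -> None:
    rows = [
        {
            "case_id": r.case_id, "conflict_situation": r.conflict_situation,
            "cluster": r.cluster, "injury_severity": r.injury_severity,
            "v_veh0_kmh": r.v_veh0, "v_vru0_kmh": r.v_vru0,
            "road_condition": r.road_condition, "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_accident_records(path: str | Path) -> list[AccidentRecord]:
    df = pd.read_csv(
        path, comment="#", dtype={"case_id": str, "source": str},
        float_precision="round_trip",
    )
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"accident-record file missing columns: {sorted(missing)}")
    return [
        AccidentRecord(
            case_id=str(row.case_id), conflict_situation=row.conflict_situation,
            cluster=row.cluster, injury_severity=row.injury_severity,
            v_veh0=float(row.v_veh0_kmh), v_vru0=float(row.v_vru0_kmh),
            road_condition=row.road_condition,
            source="" if pd.isna(row.source) else str(row.source),
        )
        for row in df.itertuples(index=False)
    ]


# -- end-to-end table fitting -------------------------------------------------

def fit_tables(
    records: Sequence[AccidentRecord],
    min_n: int = 3,
    cluster_shares: Mapping[str, Mapping[str, float]] | None = None,
    ipf_tol: float = 1e-8,
) -> ProbabilityTables:
    """Estimate all probability tables from accident records.

    Within each (severity, cluster), the source x conflict-situation counts
    are fused by IPF (the fused table matches per-source totals and the
    pooled conflict-situation totals), then normalized to a within-cluster
    distribution.  Cluster shares default to the empirical share of records
    per cluster and severity; pass base-level shares to weight to a larger
    reference population.  Speed distributions are fitted per stratum and
    subject wherever at least ``min_n`` positive samples exist.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "cs": [r.conflict_situation for r in records],
            "cluster": [r.cluster for r in records],
            "sev": [r.injury_severity for r in records],
            "rc": [r.road_condition for r in records],
            "v_veh": [r.v_veh0 for r in records],
            "v_vru": [r.v_vru0 for r in records],
            "source": [r.source for r in records],
        }
    )
    df = df[~df["cluster"].isin(EXCLUDED_CLUSTERS)]
    if df.empty:
        raise ValueError("no records left after cluster exclusion")

    p_is = severity_probabilities(df["sev"].value_counts().to_dict())

    # within-cluster conflict-situation distributions via IPF source fusion
    within: dict[tuple[str, str], dict[str, float]] = {}
    for (sev, cluster), grp in df.groupby(["sev", "cluster"], sort=True):
        pivot = grp.pivot_table(index="source", columns="cs", values="v_veh",
                                aggfunc="count", fill_value=0)
        seed = ContingencyTable(
            cells=pivot.to_numpy(dtype=float),
            row_margins=pivot.sum(axis=1).to_numpy(dtype=float),
            col_margins=pivot.sum(axis=0).to_numpy(dtype=float),
            row_labels=tuple(pivot.index), col_labels=tuple(pivot.columns),
        )
        fused = ipf(seed, tol=ipf_tol)
        col_totals = fused.cells.sum(axis=0)
        within[(sev, cluster)] = {
            cs: float(t / col_totals.sum()) for cs, t in zip(fused.col_labels, col_totals)
        }

    if cluster_shares is None:
        cluster_shares = {
            sev: normalize_cluster_shares(grp["cluster"].value_counts().to_dict())
            for sev, grp in df.groupby("sev")
        }
    else:
        cluster_shares = {s: normalize_cluster_shares(b) for s, b in cluster_shares.items()}
    p_cs_flat = conflict_probabilities(within, cluster_shares)
    p_cs_given_is: dict[str, dict[str, float]] = {}
    for (sev, cs), p in p_cs_flat.items():
        p_cs_given_is.setdefault(sev, {})[cs] = p

    p_rc: dict[tuple[str, str], dict[str, float]] = {}
    speed_dists: dict[tuple[str, str, str], WeibullParams] = {}
    for (sev, cs), grp in df.groupby(["sev", "cs"], sort=True):
        counts = grp["rc"].value_counts().to_dict()
        total = sum(counts.values())
        p_rc[(sev, cs)] = {rc: counts.get(rc, 0) / total for rc in ROAD_CONDITIONS}
        for subject, col in (("vehicle", "v_veh"), ("vru", "v_vru")):
            try:
                speed_dists[(sev, cs, subject)] = fit_weibull(
                    grp[col].to_numpy(), min_n=min_n, stratum=(cs, sev), subject=subject
                )
            except InsufficientDataError:
                continue  # stratum stays without a fitted distribution

    return ProbabilityTables(
        p_is=p_is, p_cs_given_is=p_cs_given_is,
        p_rc_given_is_cs=p_rc, speed_dists=speed_dists,
    )
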