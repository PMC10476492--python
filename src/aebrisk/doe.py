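"""MaxPro space-filling selection of the in-crash simulation matrix.

The maximum-projection (MaxPro) criterion for a design D of m points in p
dimensions is

    psi(D) = [ (1/C(m,2)) * sum_{i<j} prod_l (x_il - x_jl)^{-2} ]^(1/p)

(lower is better).  Designs built on candidate sets whose points share grid
coordinates would make psi infinite, so every squared difference is
regularized by a small additive constant before inversion.

Selection follows a two-phase probability-weighted scheme: a fraction of
the design (default 60%) is picked greedily from the candidates at or
above the median occurrence probability, the remainder greedily from all
candidates.  The greedy step adds whichever candidate minimizes psi of the
running design; the seed point is the highest-probability candidate and
ties break toward the lowest candidate index, so the selection is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import CollisionScenario

EPS = 1e-12  # coordinate-tie regularization of squared differences


@dataclass
class Design:
    candidate_points: np.ndarray  # (n, p), min-max scaled to [0, 1]
    probabilities: np.ndarray  # (n,)
    selected: list[int] = field(default_factory=list)  # ordered candidate indices

    @property
    def points(self) -> np.ndarray:
        return self.candidate_points[self.selected]


def maxpro_criterion(points: np.ndarray, eps: float = EPS) -> float:
    """Evaluate psi(D); m >= 2 points required, lower is better."""
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("maxpro criterion needs at least 2 points")
    m, p = x.shape
    iu = np.triu_indices(m, k=1)
    diff2 = (x[iu[0]] - x[iu[1]]) ** 2 + eps
    inv_prod = (1.0 / diff2).prod(axis=-1)
    return float((inv_prod.sum() / comb(m, 2)) ** (1.0 / p))


def minmax_scale(points: np.ndarray) -> np.ndarray:
    """Per-dimension min-max scaling over the candidate set; constant
    dimensions map to 0."""
    x = np.asarray(points, dtype=float)
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng = np.where(rng > 0, rng, 1.0)
    return (x - lo) / rng


def _greedy_extend(
    scaled: np.ndarray,
    selected: list[int],
    pair_sums: np.ndarray,
    pool: np.ndarray,
    n_add: int,
    eps: float,
) -> None:
    """Greedily append n_add pool candidates, minimizing the running
    pairwise inverse-product sum (equivalent to minimizing psi at each
    step).  pair_sums[c] caches sum over current design of the
    inverse-product term between candidate c and each selected point."""
    chosen = np.zeros(scaled.shape[0], dtype=bool)
    chosen[selected] = True
    for _ in range(n_add):
        avail = pool[~chosen[pool]]
        if avail.size == 0:
            raise ValueError("candidate pool exhausted")
        best = avail[np.argmin(pair_sums[avail])]
        selected.append(int(best))
        chosen[best] = True
        contrib = 1.0 / ((scaled - scaled[best]) ** 2 + eps).prod(axis=1)
        pair_sums += contrib


def select(
    clusters: Sequence[CollisionScenario],
    n_total: int = 50,
    high_fraction: float = 0.6,
    high_quantile: float = 0.5,
    eps: float = EPS,
) -> Design:
    """Two-phase probability-weighted MaxPro selection.

    Phase 1 draws ``round(high_fraction * n_total)`` points from the
    candidates whose occurrence probability is at or above the
    ``high_quantile`` probability quantile (count-based); phase 2 continues
    greedily over all candidates until ``n_total`` points are selected.
    """
    if not clusters:
        raise ValueError("no candidate clusters")
    points = np.array([c.representative for c in clusters], dtype=float)
    probs = np.array([c.probability for c in clusters], dtype=float)
    n = len(clusters)
    if n_total > n:
        raise ValueError(f"cannot select {n_total} from {n} candidates")
    scaled = minmax_scale(points)

    threshold = float(np.quantile(probs, high_quantile))
    high_pool = np.nonzero(probs >= threshold)[0]
    all_pool = np.arange(n)
    n_high = min(int(round(high_fraction * n_total)), n_total, high_pool.size)

    # seed: highest-probability candidate, ties to the lowest index
    seed = int(np.argmax(probs))
    selected = [seed]
    pair_sums = 1.0 / ((scaled - scaled[seed]) ** 2 + eps).prod(axis=1)

    if n_high > len(selected):
        _greedy_extend(scaled, selected, pair_sums, high_pool, n_high - len(selected), eps)
    if n_total > len(selected):
        _greedy_extend(scaled, selected, pair_sums, all_pool, n_total - len(selected), eps)
    return Design(candidate_points=scaled, probabilities=probs, selected=selected)


DOE_COLUMNS = [
    "selection_order", "candidate_index",
    "v_veh_mid", "v_vru_mid", "angle_mid", "cp_mid", "probability",
]


def write_design(
    design: Design, clusters: Sequence[CollisionScenario], path: str | Path
) -> None:
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
    pd.DataFrame(rows, columns=DOE_COLUMNS).to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
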