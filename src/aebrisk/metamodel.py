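"""Gaussian-process surrogate of per-criterion injury risk.

One independent Gaussian-process regressor (Matern covariance) is trained
per injury criterion, mapping the four collision-scenario coordinates
(vehicle collision speed, pedestrian collision speed, collision angle,
collision point) to the criterion's risk.  Inputs are min-max scaled to
[0, 1] per dimension; predictions are clamped to [0, 1].

The train-size sweep refits the surrogate on growing prefixes of the
space-filling selection order and reports, per training size, the test-set
RMSE per criterion and the absolute error of the probability-weighted
overall risk against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .injury import overall_risk


@dataclass
class SurrogateConfig:
    nu: float = 1.5  # Matern smoothness
    optimizer_restarts: int = 1000
    normalize_output: bool = True
    random_seed: int = 42
    alpha: float = 1e-10  # jitter; keeps noise-free interpolation

    def __post_init__(self) -> None:
        if self.optimizer_restarts < 1:
            raise ValueError("optimizer_restarts must be >= 1")


@dataclass
class TrainedSurrogate:
    gp: GaussianProcessRegressor
    x_min: np.ndarray
    x_range: np.ndarray
    criterion: str = ""

    def scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.x_min.size:
            raise ValueError(
                f"expected {self.x_min.size}-dimensional inputs, got shape {X.shape}"
            )
        return (X - self.x_min) / self.x_range


def train(
    X: np.ndarray,
    y: Sequence[float],
    cfg: SurrogateConfig | None = None,
    scaling_reference: np.ndarray | None = None,
    criterion: str = "",
) -> TrainedSurrogate:
    """Fit one surrogate; deterministic for a fixed random seed.

    ``scaling_reference`` optionally supplies the point set that defines
    the min-max scaling (e.g. the full cluster table), so that train and
    prediction inputs share one scaler.
    """
    cfg = cfg or SurrogateConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two training points")
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    # duplicate inputs with conflicting targets cannot be interpolated noise-free
    order = np.lexsort(X.T)
    Xs, ys = X[order], y[order]
    dup = np.all(np.isclose(Xs[1:], Xs[:-1]), axis=1)
    if np.any(dup & ~np.isclose(ys[1:], ys[:-1])):
        raise ValueError("duplicate training inputs with conflicting targets")

    ref = np.asarray(scaling_reference, dtype=float) if scaling_reference is not None else X
    x_min = ref.min(axis=0)
    x_range = ref.max(axis=0) - x_min
    x_range = np.where(x_range > 0, x_range, 1.0)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.ones(X.shape[1]), length_scale_bounds=(1e-2, 1e2), nu=cfg.nu
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=cfg.alpha,
        normalize_y=cfg.normalize_output,
        n_restarts_optimizer=cfg.optimizer_restarts,
        random_state=cfg.random_seed,
    )
    surrogate = TrainedSurrogate(gp=gp, x_min=x_min, x_range=x_range, criterion=criterion)
    gp.fit(surrogate.scale(X), y)
    return surrogate


def predict(s: TrainedSurrogate, X: np.ndarray) -> np.ndarray:
    """Predict risks at new collision-scenario coordinates, clamped to [0, 1]."""
    return np.clip(s.gp.predict(s.scale(X)), 0.0, 1.0)


def rmse(pred: Sequence[float], actual: Sequence[float]) -> float:
    """Root-mean-square error between predicted and actual values."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def sweep_sizes(
    n_cases: int,
    coarse_step: int = 10,
    fine_range: tuple[int, int] | None = None,
    fine_step: int = 1,
) -> list[int]:
    """Training sizes for the sweep: coarse steps over the full range plus
    an optional finely sampled interval."""
    sizes = set(range(coarse_step, n_cases + 1, coarse_step))
    if fine_range is not None:
        lo, hi = fine_range
        if lo < 2 or hi > n_cases:
            raise ValueError(f"fine_range {fine_range} outside available cases (2..{n_cases})")
        sizes.update(range(lo, hi + 1, fine_step))
    return sorted(s for s in sizes if 2 <= s <= n_cases)


def train_size_sweep(
    X: np.ndarray,
    risks: Mapping[str, Sequence[float]],
    probabilities: Sequence[float],
    cfg: SurrogateConfig | None = None,
    coarse_step: int = 10,
    fine_range: tuple[int, int] | None = None,
    fine_step: int = 1,
    sizes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Verification sweep over the number of training simulations.

    ``X`` holds the selected cases in space-filling selection order;
    ``risks`` maps each criterion to its per-case ground-truth risk;
    ``probabilities`` are the cases' occurrence probabilities.  For each
    training size n the surrogate is fitted on the first n cases and
    evaluated on the remaining cases (RMSE per criterion); the overall-risk
    error compares the probability-weighted overall risk of the
    predictions with the ground truth over the full case set.  When n
    equals the number of cases the test RMSE is undefined and flagged NaN.
    """
    X = np.asarray(X, dtype=float)
    probs = np.asarray(probabilities, dtype=float)
    n_cases = X.shape[0]
    if probs.size != n_cases:
        raise ValueError("probabilities length mismatch")
    cfg = cfg or SurrogateConfig()
    if sizes is None:
        sizes = sweep_sizes(n_cases, coarse_step, fine_range, fine_step)

    rows = []
    for n in sizes:
        per_crit_rmse: dict[str, float] = {}
        per_crit_err: dict[str, float] = {}
        for crit, y in risks.items():
            y = np.asarray(y, dtype=float)
            surrogate = train(X[:n], y[:n], cfg, scaling_reference=X, criterion=crit)
            pred_all = predict(surrogate, X)
            per_crit_rmse[crit] = (
                rmse(pred_all[n:], y[n:]) if n < n_cases else float("nan")
            )
            per_crit_err[crit] = abs(
                overall_risk(probs, pred_all) - overall_risk(probs, y)
            )
        row = {
            "n_train": n,
            "mean_rmse": float(np.nanmean(list(per_crit_rmse.values()))) if n < n_cases else float("nan"),
            "mean_overall_risk_error": float(np.mean(list(per_crit_err.values()))),
        }
        row.update({f"rmse_{c}": v for c, v in per_crit_rmse.items()})
        row.update({f"overall_risk_error_{c}": v for c, v in per_crit_err.items()})
        rows.append(row)
    return pd.DataFrame(rows)
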