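"""Injury-criterion evaluation.

Implements the per-criterion risk computations applied to in-crash
channel outputs:

* channel-frequency-class (CFC) filtering: phaseless two-pass second-order
  Butterworth low-pass per the crash-test channel-class convention
  (nominal cutoff 2.0775 x CFC), unit DC gain;
* HIC — windowed maximization of duration x (mean resultant head
  acceleration in g)^2.5;
* DAMAGE — a damped second-order oscillator per axis driven by head
  angular acceleration; the metric is a scale factor times the peak
  resultant relative displacement;
* strain-based fracture risks via monotone risk curves (Weibull CDF,
  lognormal CDF or logistic families);
* risk of 3+ fractured ribs via the exact Poisson-binomial distribution of
  independent per-rib fracture events;
* P_joint combination across body regions and the probability-weighted
  overall risk across collision scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, signal, stats

#: default criterion set: one entry per collision scenario and anthropometry
CRITERIA = (
    "skull",
    "brain_ais1", "brain_ais2", "brain_ais3", "brain_ais4",
    "ribs_3plus",
    "prox_femur_l", "prox_femur_r",
    "femur_shaft_l", "femur_shaft_r",
    "tibia_shaft_l", "tibia_shaft_r",
)

ANTHROPOMETRIES = ("F50", "M50")


@dataclass
class Channel:
    """Uniformly sampled time series (scalar or 3-axis)."""

    t: np.ndarray  # [s]
    values: np.ndarray  # (n,) or (n, 3)
    kind: str = "linear_acc_g"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("channel needs at least two samples")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("channel must be uniformly sampled")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("channel values must be finite")
        if self.values.shape[0] != self.t.size:
            raise ValueError("time and value lengths differ")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


CFC_CLASSES = (60, 180, 600, 1000)


def cfc_filter(ch: Channel, cfc_class: int) -> Channel:
    """Phaseless channel-frequency-class low-pass filter.

    A second-order Butterworth applied forward and backward (zero phase,
    effective fourth order, unit DC gain) with the conventional nominal
    cutoff of 2.0775 x CFC in Hz.
    """
    if cfc_class not in CFC_CLASSES:
        raise ValueError(f"cfc_class must be one of {CFC_CLASSES}")
    cutoff = 2.0775 * cfc_class
    if ch.fs < 10.0 * cfc_class:
        raise ValueError(
            f"sampling rate {ch.fs:.0f} Hz too coarse for CFC{cfc_class} "
            f"(need >= {10 * cfc_class} Hz)"
        )
    sos = signal.butter(2, cutoff, fs=ch.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ch.values, axis=0)
    return Channel(t=ch.t, values=filtered, kind=ch.kind)


def hic(accel: Channel, window_ms: float = 15.0) -> float:
    """Head Injury Criterion of a resultant acceleration channel in g.

    HIC = max over t2 - t1 <= window of (t2 - t1) * [mean accel]^2.5,
    maximized over all sample pairs on the sampling grid.
    """
    a = np.asarray(accel.values, dtype=float)
    if a.ndim != 1:
        raise ValueError("hic expects a resultant (1-D) channel")
    if a.size == 0:
        raise ValueError("empty channel")
    a = np.maximum(a, 0.0)
    dt = accel.dt
    cum = np.concatenate(([0.0], integrate.cumulative_trapezoid(a, dx=dt)))
    k_max = min(int(round(window_ms / 1000.0 / dt)), a.size - 1)
    if k_max < 1:
        raise ValueError("window shorter than one sampling interval")
    best = 0.0
    for k in range(1, k_max + 1):
        d_int = cum[k:] - cum[:-k]
        dur = k * dt
        best = max(best, dur * float((d_int / dur).max()) ** 2.5)
    return best


@dataclass
class DamageParams:
    """Constants of the brain-deformation oscillator.

    The head angular acceleration drives, per axis, a unit mass on a
    damped spring; displacements are coupled only through the resultant.
    Defaults are the published model constants; calibrated studies pin
    their own.
    """

    mass: float = 1.0  # [kg]
    stiffness: tuple[float, float, float] = (32142.0, 23493.0, 16935.0)  # [N/m]
    damping_ratio_factor: float = 0.0059  # C = factor * K [s]
    scale: float = 2.9903  # metric per metre of peak resultant displacement [1/m]


def damage(ang_acc: Channel, params: DamageParams | None = None) -> float:
    """DAMAGE metric from a 3-axis angular-acceleration channel [rad/s^2].

    Integrates m * d'' + c * d' + k * d = m * u'' per axis with classic
    fourth-order Runge-Kutta at the channel step (linear interpolation of
    the drive at half steps) and returns scale * max_t ||d(t)||.
    """
    params = params or DamageParams()
    u = np.asarray(ang_acc.values, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3:
        raise ValueError("damage expects a 3-axis channel (n, 3)")
    m = params.mass
    k = np.asarray(params.stiffness, dtype=float)
    c = params.damping_ratio_factor * k
    dt = ang_acc.dt
    n = u.shape[0]

    def deriv(state: np.ndarray, drive: np.ndarray) -> np.ndarray:
        d, dd = state[0], state[1]
        return np.stack([dd, drive - (c * dd + k * d) / m])

    state = np.zeros((2, 3))
    peak = 0.0
    for i in range(n - 1):
        u0, u1 = u[i], u[i + 1]
        um = 0.5 * (u0 + u1)
        k1 = deriv(state, u0)
        k2 = deriv(state + 0.5 * dt * k1, um)
        k3 = deriv(state + 0.5 * dt * k2, um)
        k4 = deriv(state + dt * k3, u1)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        peak = max(peak, float(np.linalg.norm(state[0])))
    return params.scale * peak


@dataclass(frozen=True)
class RiskCurve:
    """Monotone map from an injury predictor to a fracture/injury probability.

    families:
      * ``weibull_cdf``: params (shape, scale)
      * ``lognormal_cdf``: params (median, log-space sigma)
      * ``logistic``: params (x50, slope) -> 1/(1 + exp(-slope (x - x50)))
    """

    family: str
    params: tuple[float, ...]
    predictor: str = ""

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "weibull_cdf":
            shape, scale = self.params
            out = stats.weibull_min.cdf(x, shape, scale=scale)
        elif self.family == "lognormal_cdf":
            median, sigma = self.params
            out = stats.lognorm.cdf(x, sigma, scale=median)
        elif self.family == "logistic":
            x50, slope = self.params
            out = 1.0 / (1.0 + np.exp(-slope * (x - x50)))
        else:
            raise ValueError(f"unknown risk-curve family {self.family!r}")
        return np.clip(out, 0.0, 1.0)


def strain_risk(mps99: float, curve: RiskCurve) -> float:
    """Fracture risk from the 99th-percentile maximum principal strain."""
    if mps99 < 0:
        raise ValueError("strain must be non-negative")
    return float(curve(mps99))


def poisson_binomial_sf(p: Sequence[float], threshold_count: int) -> float:
    """P(N >= threshold_count) for independent Bernoulli trials, by exact
    dynamic programming over the count distribution."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1.0 - pi
    return float(pmf[threshold_count:].sum())


def rib_fracture_risk(
    per_rib_strain: Mapping[str, float],
    curve: RiskCurve,
    threshold_count: int = 3,
) -> float:
    """Risk of >= threshold_count fractured ribs.

    Per-rib fracture probabilities come from the strain risk curve; ribs
    fracture independently, so the fractured-rib count follows a
    Poisson-binomial distribution evaluated exactly.
    """
    if threshold_count > len(per_rib_strain):
        raise ValueError("threshold_count exceeds the number of instrumented ribs")
    strains = np.asarray(list(per_rib_strain.values()), dtype=float)
    if np.any(strains < 0):
        raise ValueError("strains must be non-negative")
    return poisson_binomial_sf(curve(strains), threshold_count)


def pjoint(region_risks: Sequence[float]) -> float:
    """Combined probability of at least one injury across body regions."""
    p = np.asarray(region_risks, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("risks must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def overall_risk(cluster_probs: Sequence[float], risks: Sequence[float]) -> float:
    """Probability-weighted overall risk over collision scenarios,
    normalized by the colliding probability mass."""
    p = np.asarray(cluster_probs, dtype=float)
    r = np.asarray(risks, dtype=float)
    if p.shape != r.shape:
        raise ValueError("cluster_probs and risks must have equal length")
    total = p.sum()
    if total <= 0:
        raise ValueError("cluster probabilities sum to zero")
    return float((p * r).sum() / total)


@dataclass
class InjuryRiskVector:
    """Per-criterion risks for one collision scenario and anthropometry."""

    risks: dict[str, float]
    anthropometry: str

    def __post_init__(self) -> None:
        if self.anthropometry not in ANTHROPOMETRIES:
            raise ValueError(f"unknown anthropometry {self.anthropometry!r}")
        for crit, r in self.risks.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"risk for {crit!r} outside [0, 1]: {r}")
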