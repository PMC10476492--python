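# Methods

This note documents the models behind `aebrisk`, the defaults and why they
were chosen, what the synthetic world does and does not emulate, and the
numerical choices that affect reproducibility.

## Accident statistics

**Speed distributions.**  Initial vehicle and pedestrian speeds are
modelled per stratum (conflict situation × injury severity × subject) as
two-parameter Weibull distributions, fitted by maximum likelihood.  The
shape parameter solves the profile likelihood equation
`Σ xᵏ ln x / Σ xᵏ − 1/k = mean(ln x)` by bracketed Brent root finding
(tolerance 1e-10, ≤ 200 iterations); the scale follows in closed form as
`(mean(xᵏ))^{1/k}`.  Samples of exactly 0 km/h are excluded before
fitting: the Weibull support is positive, and a stationary pedestrian is
representable by the lowest percentile of the speed grid rather than by
the fit.  A stratum with fewer than 3 positive samples is rejected
(`InsufficientDataError`) and simply carries no distribution — it then
contributes no scenarios to the catalog.  A Kolmogorov–Smirnov statistic
is available per fit for informational purposes; goodness of fit is never
used to reject a stratum, since sparse strata would fail such a screen for
sample-size reasons alone.  When several source databases are pooled, the
records are concatenated without weights.

**Categorical probabilities.**  Severity probabilities are normalized
counts.  Conflict-situation probabilities are estimated within clusters of
similar conflict situations: per (severity, cluster) the source × conflict
situation count table is fused by iterative proportional fitting (IPF,
alternating row/column scaling; margin tolerance 1e-8, ≤ 10 000
iterations — the tables are tiny, so a tight tolerance is free), and the
fused within-cluster distribution is then multiplied by the cluster's
share of accidents.  Zero seed cells stay zero, so the fit preserves the
seed's odds ratios.  Cluster labels `Unspecified` and `Others` are dropped
before share normalization: they do not describe a simulatable motion
pattern.  Structurally infeasible margins (an all-zero row with a positive
target) raise immediately rather than spinning to the iteration cap.

## Scenario catalog

Each fitted speed CDF is split into equal-probability percentile intervals
(5 % vehicle, 10 % pedestrian); the grid speed of an interval is the
inverse CDF at the *interval midpoint* (2.5 %, 7.5 %, … 97.5 % for the 5 %
step).  Midpoints avoid the degenerate 0th and 100th quantiles.  This
placement choice matters to anyone comparing against an externally
published catalog built with a different convention.

The occurrence model assigns no distribution to the collision point, yet
each scenario must specify one.  The scenario probability is therefore
split uniformly over the configured collision-point values (default
−40 %, −20 %, 0 %, +20 %, +40 % of the front width — symmetric coverage of
the binning range), keeping the catalog mass at exactly 1.  Scenario IDs
are a deterministic, lexicographically sortable composition of all
parameters (`{CS}_{IS}_{RC}_v{veh:05.1f}_p{vru:04.1f}_cp{cp:+03d}`), so
two builds from identical tables are byte-identical.

## Pre-crash simulation

The world is planar: the vehicle drives straight along +x; the pedestrian
walks a straight path at a conflict-situation-specific heading.  Turning
conflict situations are approximated by their collision-local straight
equivalent (a heading angle, configurable per conflict situation): the
curvature of the vehicle path mainly affects sensor geometry long before
braking, while the straight equivalent keeps the closed-form braking
oracles exact and the whole catalog simulation vectorizable.  Default
templates use pedestrian headings with a non-positive forward component
(perpendicular, or obliquely facing the vehicle), so every constructed
scenario is a genuine closing conflict.

The start state places both participants so that at constant speeds the
pedestrian centre meets the vehicle front plane at the target collision
point exactly `lead_time` seconds after start (default 4 s).  When a
sensor is present the start is pushed back until the pedestrian begins
outside sensor range, so slow-vehicle scenarios start earlier.

**Sensor and trigger.**  The geometric sensor (range 60 m, field of view
60°, mounted 0.25 m behind the most frontal point) sees the pedestrian
when both tangent angles of the pedestrian disc, quantized to the 0.5°
azimuth resolution, lie inside the field of view.  Detection requires 150
ms of continuous visibility and then latches.  TTC is the time until the
constant-velocity pedestrian-centre path crosses the front-edge segment
under constant vehicle speed; braking is commanded when the confirmed TTC
drops to the 1.0 s trigger.

**Braking.**  The commanded deceleration is zero during the brake delay,
then ramps at the brake gradient until it saturates at μ·g (μ = 0.8 dry /
0.5 non-dry).  Delay 0.15 s and gradient 35 m/s³ are typical values in the
prospective-assessment literature; all four are configuration fields.  The
braked speed is evaluated from the *closed-form integral* of this
delay/ramp/saturation profile, anchored at the exact instant the TTC
crossed the trigger threshold (back-dated within the 10 ms step — exact,
because speeds are constant pre-trigger, and never earlier than the
detection time).  This removes the zero-order-hold discretization error
that a per-step Euler update would introduce, so the residual collision
speed matches constant-deceleration kinematics to well under 0.5 km/h and
halving the time step changes nothing material.

**Contact.**  A collision is recorded when the pedestrian centre crosses
the front plane within the front-edge span widened by the pedestrian
radius (0.3 m); crossing time, speed and lateral position are interpolated
within the step.  This centre-crossing convention is the one consistent
with the TTC definition and with constant-deceleration braking-distance
arithmetic.  A vehicle braked to a full stop ends its run as *avoided* —
a pedestrian subsequently walking into a stationary front plane is not a
vehicle crash.  Scenarios that neither collide nor resolve are cut off at
`lead_time + 10 s`.

Collision-point sign: positive toward the vehicle's right.  Collision
angle: pedestrian heading minus vehicle heading, counter-clockwise,
wrapped to [0°, 360°).

## Collision scenarios and in-crash selection

Collision outcomes are binned left-closed/right-open on the fixed grid
(vehicle speed 5 km/h over 0–120, pedestrian speed 1 km/h over 0–20,
angle 30° over 0–360, collision point 5 % over ±50), with the global
upper endpoint closed — the standard histogram convention.  Because the
simulation is deterministic, a bin's probability is the plain sum of its
members' occurrence probabilities.  The bin midpoint serves as the
cluster representative (the alternative, probability-weighted within-bin
means, would make the representative depend on the catalog resolution).

The in-crash matrix is selected with the maximum-projection (MaxPro)
criterion `ψ(D) = [C(m,2)⁻¹ Σ_{i<j} Π_l (x_il − x_jl)⁻²]^{1/p}` on
min-max-scaled coordinates.  Construction is greedy: seed at the
highest-probability candidate, then repeatedly add the candidate
minimizing ψ, ties broken toward the lowest index — reproducible and
near-optimal for candidate-set selection, without the complexity of
exchange or annealing optimizers.  Squared coordinate differences are
regularized by +1e-12 before inversion because clustered candidates share
grid coordinates.  The two-phase scheme takes 60 % of the points from
candidates at or above the count-based probability median ("upper half by
occurrence probability") and the rest from all candidates.

## Injury criteria

* **CFC filtering**: second-order Butterworth at the conventional nominal
  cutoff 2.0775 × CFC, applied forward and backward (zero phase, unit DC
  gain).  Sampling must be at least 10 × the channel class.
* **HIC**: windowed maximization of `(t₂−t₁)·[mean a]^2.5` over all
  sample pairs within the window (default 15 ms; 36 ms selectable),
  computed from the cumulative trapezoid integral.
* **DAMAGE**: per axis, a unit mass on a damped spring driven by head
  angular acceleration (`m δ̈ + c δ̇ + k δ = m ü`); the metric is the scale
  factor times the peak resultant displacement.  Integration is classic
  RK4 at the channel step with the drive linearly interpolated at half
  steps; a quarter-step refinement moves the result by < 0.1 %.  The
  default constants (k = 32 142 / 23 493 / 16 935 N/m, C = 0.0059·K,
  B = 2.9903 m⁻¹) are the published model values; calibrated studies
  should pin their own.
* **Rib fractures**: per-rib fracture probabilities from a strain risk
  curve, combined under independence into the exact Poisson-binomial
  probability of ≥ 3 fractures via dynamic programming over the count
  distribution.
* **Strain risks**: monotone risk-curve families (Weibull CDF, lognormal
  CDF, logistic).  Curve parameters are configuration entries — published
  calibrations for specific human-body models are not bundled, so the
  defaults used in tests are synthetic placeholders and every test pins
  the curve it uses.
* **Combination**: across body regions `P_joint = 1 − Π(1 − pᵢ)`; across
  collision scenarios the probability-weighted overall risk
  `Σ pᵢ rᵢ / Σ pᵢ`, normalized by the colliding probability mass so that
  baseline and AEB conditions compare the *residual crash populations*.
  The un-normalized product (absolute risk, which additionally credits
  avoided scenarios) is reported alongside; the AEB's absolute risk can
  never exceed the baseline's, while its normalized risk measures only
  impact mitigation.

## Metamodel

One Gaussian-process regressor per injury criterion maps the four
collision-scenario coordinates to risk: Matérn kernel (ν = 1.5 — risk
surfaces are smooth but not analytic; configurable), constant-kernel
amplitude, output normalization on, jitter 1e-10 so noise-free training
points are interpolated to ~1e-3.  Inputs are min-max scaled to [0,1] per
dimension over a shared reference set (normally the full cluster table).
Predictions are clamped to [0,1].  The kernel-hyperparameter optimizer
default of 1000 restarts follows common surrogate practice; the pipeline
configuration uses 5 restarts, which on these smooth 4-D surfaces finds
the same optimum — raise it when fitting rougher responses.

The train-size sweep refits each criterion's surrogate on growing
prefixes of the MaxPro selection order, reporting per size the test-set
RMSE (`√(Σ(ŷ−y)²/n)` over the not-yet-selected cases) and the absolute
error of the probability-weighted overall risk evaluated over the full
case set.  When the training prefix is the whole set the test RMSE is
undefined and flagged NaN.

## Synthetic world

The default generator world has five conflict situations in three
clusters (straight crossing left/right, oblique crossing left/right,
turning) and three severities P(slight/severe/fatal) = 0.70/0.25/0.05.
Vehicle-speed Weibull scales are 32/48/65 km/h (shape 2.0/2.2/2.4) for
slight/severe/fatal — severer outcomes come from faster traffic —
and pedestrian scales 5–6 km/h, with small per-conflict-situation
multipliers.  Severe and fatal records only populate the two straight-
crossing situations, mirroring the sparsity of real in-depth data (those
strata alone get fitted distributions).  Under the default AEB roughly
half of the scenarios (about a third of the probability mass) remain
unavoidable, which keeps clustering, selection and the metamodel richly
populated.

The surrogate injury response is a deterministic logistic function of the
collision-scenario coordinates per criterion and anthropometry:
`logit = b₀ + b_v·v̂ + b_cp·|CP| + b_a·|A−90°|`, strictly increasing in
collision speed, with intercepts encoding the field-observed direction of
sex differences (average female: higher proximal-femur risk; average
male: higher rib and skull fracture risk).  Optional Gaussian noise on
the logit supports robustness studies of the Gaussian process.  A signal
emitter produces half-sine head pulses (peak linear acceleration 2 g per
km/h, 10 ms duration, 10 kHz) and speed-proportional strain scalars so
the signal-level injury chain can be exercised end to end.

What the synthetic world does **not** emulate: body kinematics
(wrap-around, head trajectory), vehicle-front stiffness, pedestrian
posture, age effects, sensor degradation, or any correlation between
speeds and road condition beyond the configured factorization.  A passing
pipeline therefore demonstrates the statistical and numerical machinery —
estimation, propagation of occurrence probability, selection, surrogate
accuracy — not the biomechanical fidelity of any particular vehicle.

## Problem sizes and reproducibility

The shipped configurations use 20 000 synthetic records, an 18 000-
scenario catalog (9 fitted strata × 20 vehicle speeds × 10 pedestrian
speeds × 2 road conditions × 5 collision points) and a 200-case
verification selection for the sweep; the test suite runs reduced worlds
(hundreds of scenarios) chosen to exercise every code path.  All
randomness flows from explicit seeds (generator seed, GP `random_state`);
wall-clock seeding is not used anywhere.  Every artifact embeds the
SHA-256 hash (truncated) of the resolved configuration, and downstream
stages refuse mismatched inputs unless explicitly overridden, so a run
directory is self-describing and reruns are byte-identical.

## Known limitations

* No driver model, evasive steering, pedestrian reaction or occlusion in
  the pre-crash world; 2-D kinematics only.
* Turning trajectories are straight-equivalent approximations.
* The sensor's TTC check uses the pedestrian-centre path against the
  front span, so grazing trajectories just outside the span can collide
  without ever triggering the system (a realistic failure mode, but a
  modelling choice).
* Rib independence in the Poisson-binomial combination ignores load
  sharing between neighbouring ribs.
* Risk-curve calibrations for specific human-body models are not
  included; results with the placeholder curves are only meaningful
  relative to each other.
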