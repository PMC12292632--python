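# Methods

This note documents the models implemented in `duotank`, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations. Every number quoted here is
computed by the test suite or by `scripts/acceptance.py`.

## Process models

**Two-zone recirculation balance.** The reactor is modelled as two
well-mixed compartments of equal liquid volume `V_L` (default 3 L)
exchanging medium at a volumetric flow `V` (default 0.3 L/min; only the
ratio `V/V_L` enters the equations), each relaxing toward the saturation
concentration `C*(φ)` with its own effective transfer coefficient:
`λ₁ = 0.0069233 s⁻¹` for the aerated/stirred zone and
`λ₂ = 0.0004899 s⁻¹` for the quiescent growth zone. All rates are per
second; a per-minute exchange flow in a config file is converted at the
I/O boundary. The system is linear for a fixed gas composition, with a
slow mode of ≈575 s and a fast mode of ≈110 s at the default constants —
this separation is what makes feedback-only control of the growth zone
sluggish and motivates the predictive injection phase.

**Transfer and saturation laws.** `kLa(φ) = a φ^m` with `a = 2.5302 s⁻¹`,
`m = 1.9139`; the equivalent dimensionless correlation
`kLa² d_B/(g ρ²) = n₁ φ^n₂` gives the exact algebraic maps `m = n₂/2`
and `a = √(n₁ g ρ²/d_B)`. Two caveats are deliberately preserved as
printed in the source system's tables rather than "corrected": the listed
gravitational acceleration is 9.0866 m/s² (likely a transcription of
9.8066 — a config override exists), and the printed `a = 2.5302` is *not*
equal to `√(n₁ g ρ²/d_B)` evaluated at the listed geometry (the unit
system of the dimensionless regression is not recoverable). Both pathways
are exposed; defaults use the printed `(a, m)` directly. The saturation
law defaults to the linear form `C* = c φ` with `c = 36.1053 mg/L`, which
is consistent with the stability-band table (its top bound is
`C*(1) = 36.11 mg/L` after rounding). The thermodynamic closed form
`C* = 32·10³·exp(d₁ ln(φ(P − P_H₂O)) − d₂)` is implemented under one
documented parse as an alternative mode; its printed constants do not
reproduce `c φ`, so it is never the default.

**Growth coupling.** Cell growth is logistic,
`dN/dt = r N (1 − N/K)`, and oxygen uptake is Monod in DO with a per-cell
coefficient: `OUR = OURmax·K_N·N·C/(K_s + C)`. The denominator grouping
of the published uptake expression is typeset ambiguously; the per-cell
Monod reading implemented here matches the accompanying text ("the impact
of cell number on oxygen uptake" enters multiplicatively). The growth
constants are not published; the defaults (`N0 = 10⁷`, `K = 10¹⁰` cells,
`r = 1.2·10⁻⁵ s⁻¹`, `OURmax = 0.5 mg/(L·s)`, `K_s = 0.5 mg/L`,
`K_N = 10⁻¹¹ cells⁻¹`) were chosen once so that the peak culture demand
(`≈ 0.046 mg/(L·s)`) raises the steady oxygen fraction needed to hold
6.5 mg/L from 0.18 to about 0.19 — a realistic actuation range — and were
not revisited afterwards.

## Integration

Fixed-step RK4 (explicit Euler available for cross-checks), default
`dt = 1 s` to match the 1 s control sampling. Where the instantaneous
rate constant exceeds the comfortable RK4 range (`kLa·dt > 0.5`, e.g.
during pure-oxygen injections in the growth study) the step is internally
subdivided. States are clamped at zero after each step and the clamp count
is reported; non-finite states abort with the offending step index. The
single-zone integrator matches the analytic exponential to ≤10⁻⁶ relative
error at `dt = 0.1 s` (tested), and the discrete delay plant uses the
exact zero-order-hold recursion, which reproduces the continuous step
response to round-off.

## Identification

All estimators are exact (≤10⁻⁹ relative error) on noise-free data
generated from their own model — that closure is the core oracle suite.
The gassing-out fit regresses `ln(C* − C)` on time over *all* samples
(the classical two-point formula is the `n = 2` special case); any sample
at or above `C*` is a domain error naming the sample. The `(λ₁, λ₂)` fit
minimises the summed squared deviation of the two-zone simulation from
both zone traces with equal weights, searching in `log₁₀ λ` from a 4×4
decade grid (10⁻⁴…10⁻¹) under bounds that keep the fixed-step simulation
stable. RMSE and R² follow the standard definitions; R² is flagged NaN
for zero-variance observations. The published experimental traces behind
the source system's RMSE/R² table are not available, so those specific
values are demonstrated at the formula level and by parameter-recovery
tests, not reproduced.

## Control design

**Reduced plant.** Linearising the feedback model
`dY/dt = a U^m (c U − Y)` about an equilibrium gives a stable first-order
system (pole `B = a U₀^m > 0`); with the sensor dead time the benchmark
plant is `G(s) = 0.25/(s + 0.1)·e^(−10s)`. The printed transfer function
carries the pole with the opposite sign (`s − B`); an unstable pole with
`B·τ = 1` sits at the classical limit of delay stabilisation and cannot be
stabilised by the printed PID gains, whereas the physical derivation
(`∂f/∂Y < 0`) is unambiguous — the stable sign is used throughout. The
dead time is treated as a sensor delay: controllers see the plant state
10 s late, and error metrics are computed on the true state.

**PID.** Positional form, derivative on the measurement, clamping
anti-windup, output limited to φ ∈ [0, 1] when driving a tank model and
unlimited when driving the abstract reduced plant. The published tunings
ship as presets: `published_initial = (0.06, 0.004, 0.45)` and
`published_final = (0.0015, 0.0005, 0.01)`.

**Ziegler–Nichols.** The ultimate gain is found by bisecting the
proportional gain between decaying and growing closed-loop oscillation of
the simulated loop (step ≈0.1 s so sampling adds negligible phase);
the period comes from zero-crossing spacing at the critical gain. The
independent frequency-domain oracle (phase crossover of
`arctan(ω/B) + τω = π`) agrees within 2% (tested). For the benchmark
plant this gives `Ku ≈ 0.905, Tu ≈ 30.9 s`; the published `Tu = 30 s`
matches the plant's phase crossover almost exactly, while the published
`Ku = 0.1247` is not consistent with the printed plant under any scaling
we could document — the package reports what the stated analysis yields.

**Simulated annealing.** Gaussian proposals per gain (scales 0.01 /
0.002 / 0.05), Metropolis acceptance, geometric cooling (T₀ = 1, factor
0.995, 2000 iterations by default), seeded and bit-reproducible; the
schedule is the package's own, as none is published. The tuned objective
is never worse than the initial one (best-seen gains are returned).

**DPPC supervisor.** Mode selection uses hysteresis between the two
published thresholds: the predictive phase runs until the delayed
measurement is within the 5% margin of the target — the stated validity
region of the linearised plant, hence of the PID — and the PID then takes
over with bumpless transfer (derivative restarted, integral set for input
continuity). Predictive mode re-engages only when the measurement leaves
the larger critical band of the stability table, and mode switches are
rate-limited to the replanning interval (30 s), so the supervisor cannot
chatter. At start-up the commanded input is the model's steady-state hold
fraction rather than zero.

**Injection planning.** On tank plants the planner forward-simulates the
two-zone model: inject `φ = 1` (pure oxygen) for `t₁` seconds — or flush
with `φ = 0` when above target — then hold the steady-state fraction
`target/C*(1)`. `t₁` is the smallest duration (bisection at 1 s
resolution; the predicted extremum is monotone in the duration, and
bisection is verified against an exhaustive grid scan) whose predicted
growth-zone extremum lands inside the margin band within a finite
prediction window (injection + 300 s), guarded so the prediction never
crosses the far side of the band. The finite window is essential: the
hold fraction alone reaches any target asymptotically, so an unbounded
horizon would always return `t₁ = 0` and the injection phase would never
engage. Coasting at the hold fraction (rather than at ambient air) makes
the predicted peak well defined on both sides of the target and arrests
the post-injection drift. On the reduced delay plant the internal model
is the plant's own exact discrete form with dead-time compensation
(rolling the model through the buffered inputs); "pure oxygen" maps to
the input whose steady state equals `C*(1)`, and the final injection step
is amplitude-trimmed so the predicted state lands exactly on the target —
which is why the benchmark overshoots are identically zero.

## Benchmarks and study sizes

* **Five-stage tracking benchmark** (`Scenario()`): targets
  0→4.0→6.5→9.0→6.5→4.0 mg/L, 600 s per stage, reduced delay plant,
  1 s sampling (3000 steps). With the `published_final` gains the pure
  PID loop is overdamped with a ≈700 s slowest pole, so it never settles
  a stage: ISE ≈ 1.96·10⁴, IAE ≈ 6.7·10³. The published benchmark values
  (ISE 4284.10/2147.12, DPPC 2233.98/1257.82) correspond to an
  oscillatory loop with a ~100–160 s effective decay, which the printed
  plant/gain combination cannot produce; the implemented DPPC is instead
  near-deadbeat on this plant (ISE ≈ 10). The robust, reproducible
  statement — and the one this package asserts in its acceptance tests —
  is the ordering: DPPC reduces both ISE and IAE by well over 30%, and
  eliminates overshoot on every transition.
* **Settling sweep**: DPPC from initial DO 0–8 mg/L (1 mg/L grid) to
  targets 4.0/6.5/9.0 mg/L on the *dual-tank* plant (27 runs of 900 s).
  The recirculation time constants, not the 10 s reduced plant, govern
  these transients; all runs settle (5% band, persistent) with a mean
  settling time of 364.5 s, close to the published 376 s average.
* **Growth study**: 15 simulated days (1.296·10⁶ control intervals) of
  DPPC regulation at 6.5 mg/L, uptake perturbed each second by a seeded
  multiplicative uniform(−10%, +10%) factor. Post-transient (after the
  first hour) the DO stays within ±0.025 mg/L of target (published bound:
  ±0.05), with a fluctuation range of ≈0.049 mg/L (published: 0.057) and
  a DO standard deviation ("stability factor") of ≈0.004. The run takes
  about one minute on one CPU.

## Synthetic data

The generator reproduces the three identification experiments with known
ground truth and additive Gaussian sensor noise (zero noise returns the
exact model curve; fixed seeds are bit-reproducible). It emulates ideal,
drift-free sensors on a uniform grid with white noise; it does not model
sensor calibration error, probe response lag, temperature/pH coupling, or
bubble/foam artifacts — so passing recovery tests demonstrate estimator
correctness, not robustness to every failure mode of real probes.

## Known limitations

* No spatial/CFD mixing, shear-stress, pH or temperature dynamics; gas
  composition is the only manipulated variable.
* The thermodynamic saturation mode implements one documented parse of an
  ambiguous closed form and is excluded from defaults.
* The bench-scale hardware results of the source system are inherently
  rig-dependent and are out of scope; only simulation studies are
  reproduced.
* The two-tank planner estimates the unmeasured stirred-zone state by
  open-loop propagation of the internal model from an equilibrated start;
  with significant plant–model mismatch an observer with measurement
  correction would be needed.
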