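# duotank

Dissolved-oxygen (DO) modelling, parameter identification and hybrid
predictive control for **dual-tank recirculating cell-culture bioreactors**.

Shear-sensitive cell cultures are often grown in a two-compartment system:
an aerated, stirred oxygen-enrichment tank and a gentle cell-growth tank,
with medium pumped between them. The separation protects the cells but
creates DO gradients and sensor/transport delays that make oxygen control
hard. `duotank` implements the full modelling-and-control loop for such a
system:

* **Process model.** Two coupled balances for the DO in the stirred zone
  `C_J` and the growth zone `C_Y`:

  ```
  dC_J/dt = (V/V_L)(C_Y − C_J) + λ₁ (C*(φ) − C_J)
  dC_Y/dt = (V/V_L)(C_J − C_Y) + λ₂ (C*(φ) − C_Y)
  ```

  where `φ` is the oxygen volume fraction of the gas feed,
  `kLa(φ) = a φ^m` is the volumetric mass-transfer coefficient
  (equivalently `kLa² d_B/(g ρ²) = n₁ φ^n₂` in dimensionless form) and
  `C*(φ) = c φ` is the saturated DO. A growth-coupled variant adds logistic
  cell growth with Monod oxygen uptake,
  `dC/dt = kLa (C* − C) − OURmax·K_N·N·C/(K_s + C)`.

* **Identification.** Estimators for every constant from plain sensor
  traces: dynamic gassing-out regression for `kLa`, log–log fits for
  `(a, m)`/`(n₁, n₂)`, the saturation constant `c` (or the thermodynamic
  pair `d₁, d₂`), and nonlinear least squares for `(λ₁, λ₂)`; all exposed
  both as functions and as small model classes whose `fit()` returns a
  results object with estimates, standard errors, RMSE/R² and `summary()`.

* **Control.** A discrete PID with measurement-delay handling around the
  reduced plant `G(s) = A/(s+B)·e^(−τs)` (defaults `A=0.25, B=0.1, τ=10 s`),
  Ziegler–Nichols initialisation from the simulated ultimate gain,
  simulated-annealing refinement, and **DPPC** (dynamic parameterized
  predictive control): while the measured DO is outside the critical
  stability band of the target, a model-predicted pure-oxygen injection
  `(φ, t₁)` drives the growth zone to the target; inside the 5% margin a
  PID takes over with bumpless transfer.

* **Evaluation.** ISE/IAE, overshoot, settling time, steady-state error
  and fluctuation range; the multi-target benchmark schedule; a 15-day
  growth-coupled regulation study with seeded oxygen-uptake disturbances.

All defaults are the fitted constants of the reference 3 L dual-tank
system (`a=2.5302, m=1.9139, c=36.1053, λ₁=0.0069233, λ₂=0.0004899`, …);
everything is overridable through a YAML/JSON config.

## Worked example

```python
import duotank as dt

# identify kLa from a (synthetic) gassing-out experiment at 50% oxygen
trace = dt.generate_synthetic_trace("gassing_out", kla=0.02, cstar=18.05,
                                    duration=120.0, noise_sd=0.05, seed=7)
res = dt.GassingOutKLa(trace, cstar=18.05).fit()
print(res.summary())
```

```
GassingOutKLa results
parameter      estimate      std.err.
kla             0.0200015     2.98e-05
RMSE = 0.0425395   R^2 = 0.999914
```

The estimate recovers the true `kLa = 0.02 s⁻¹` to 0.01% from a noisy
trace (RMSE ≈ the 0.05 mg/L sensor noise).

```python
# compare plain PID with DPPC on the five-stage benchmark schedule
sc = dt.Scenario()           # 0 → 4.0 → 6.5 → 9.0 → 6.5 → 4.0 mg/L, 600 s each
_, _, pid = dt.run_scenario(sc, controller="pid")
_, stages, dppc = dt.run_scenario(sc, controller="dppc")
print(f"PID  ISE={pid.ise:8.2f}  IAE={pid.iae:7.2f}")
print(f"DPPC ISE={dppc.ise:8.2f}  IAE={dppc.iae:7.2f}")
print("DPPC overshoot per stage [%]:",
      [round(s.overshoot_pct, 2) for s in stages])
```

```
PID  ISE=19590.61  IAE=6743.85
DPPC ISE=    9.88  IAE=   7.88
DPPC overshoot per stage [%]: [0.0, 0.0, 0.0, 0.0, 0.0]
```

With the published final PID gains the pure feedback loop is far too slow
for 600 s target stages (its slowest closed-loop pole has a ~700 s time
constant), while the predictive injection phase reaches each target within
seconds of the sensor delay and hands over to the PID with zero overshoot.
The same supervisor on the slow dual-tank plant settles the full
27-run initial-condition sweep (initial DO 0–8 mg/L, targets 4.0/6.5/9.0
mg/L) with a mean settling time of 364.5 s.

A command-line interface mirrors the library:

```sh
duotank --seed 1 --out runs/bench benchmark
duotank --out runs/fit make-synthetic --kind gassing_out
duotank --out runs/fit fit-kla runs/fit/synthetic_trace.csv --cstar 7.58
duotank --out runs/growth growth-sim --days 15
```

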