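"""Reduced plant, PID, Ziegler-Nichols, annealing, bands and planners."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from duotank import (
    DEFAULT_BANDS,
    DPPCConfig,
    FOPDT,
    PIDGains,
    PIDState,
    PID_PRESETS,
    RecircParams,
    SAConfig,
    SaturationLaw,
    StabilityBands,
    TankState,
    ZNResult,
    closed_loop_fopdt,
    critical_band,
    fopdt_simulate,
    linearize_feedback_model,
    pid_step,
    predict_injection,
    sa_tune_pid,
    zn_initial_gains,
    zn_ultimate_gain,
)
from duotank.control import DelayLine


def ultimate_gain_oracle(plant: FOPDT):
    """Frequency-domain oracle: phase crossover of A/(s+B) e^(-tau s)."""
    w = brentq(lambda w: math.atan(w / plant.B) + plant.tau * w - math.pi,
               1e-9, 1e3)
    return math.sqrt(w * w + plant.B ** 2) / plant.A, 2.0 * math.pi / w


class TestLinearisation:
    def test_equilibrium_residual_vanishes(self):
        a, m, c, U0 = 1.7, 2.1, 30.0, 0.3
        Y0 = c * U0
        assert a * U0 ** m * (c * U0 - Y0) == 0.0

    def test_unit_case(self):
        plant = linearize_feedback_model(a=1.0, m=1.0, c=1.0, U0=1.0, Y0=1.0)
        assert plant.A == pytest.approx(1.0)
        assert plant.B == pytest.approx(1.0)

    def test_pole_is_independent_of_c_and_y0(self):
        p1 = linearize_feedback_model(2.0, 1.5, 10.0, 0.4, 1.0)
        p2 = linearize_feedback_model(2.0, 1.5, 99.0, 0.4, 7.0)
        assert p1.B == pytest.approx(p2.B)
        assert p1.B == pytest.approx(2.0 * 0.4 ** 1.5)

    @pytest.mark.parametrize("a,m,c,U0,Y0", [
        (1.0, 1.0, 1.0, 1.0, 1.0),
        (2.5302, 1.9139, 36.1053, 0.2, 5.0),
        (0.7, 2.4, 12.0, 0.55, 3.3),
    ])
    def test_matches_symbolic_differentiation(self, a, m, c, U0, Y0):
        import sympy as sp

        U, Y = sp.symbols("U Y", positive=True)
        f = a * U ** m * (c * U - Y)
        A_sym = float(sp.diff(f, U).subs({U: U0, Y: Y0}))
        B_sym = float(-sp.diff(f, Y).subs({U: U0, Y: Y0}))
        plant = linearize_feedback_model(a, m, c, U0, Y0)
        assert plant.A == pytest.approx(A_sym, rel=1e-12)
        assert plant.B == pytest.approx(B_sym, rel=1e-12)


class TestFOPDTSimulate:
    def test_zero_input_zero_output(self):
        plant = FOPDT()
        y = fopdt_simulate(plant, np.zeros(100), dt=1.0, y0=0.0)
        assert np.all(y == 0.0)

    def test_unit_step_matches_continuous_response(self):
        plant = FOPDT(A=0.25, B=0.1, tau=10.0)
        n = 400
        y = fopdt_simulate(plant, np.ones(n), dt=1.0)
        t = np.arange(n)
        exact = np.where(t > 10, 2.5 * (1.0 - np.exp(-0.1 * (t - 10.0))), 0.0)
        assert np.abs(y - exact).max() <= 1e-9
        assert y[10] == 0.0
        assert abs(y[-1] - 2.5) < 1e-3

    def test_output_before_dead_time_ignores_input(self, rng):
        plant = FOPDT(tau=10.0)
        u1 = rng.normal(size=50)
        u2 = rng.normal(size=50)
        y1 = fopdt_simulate(plant, u1)
        y2 = fopdt_simulate(plant, u2)
        assert np.allclose(y1[:11], y2[:11])

    def test_superposition_on_ramps(self, rng):
        plant = FOPDT(A=0.4, B=0.05, tau=4.0)
        ramp = np.linspace(0.0, 1.0, 200)
        step = np.ones(200)
        combined = fopdt_simulate(plant, 2.0 * ramp + 3.0 * step)
        parts = 2.0 * fopdt_simulate(plant, ramp) + 3.0 * fopdt_simulate(plant, step)
        assert np.abs(combined - parts).max() <= 1e-9

    def test_fractional_dead_time_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            fopdt_simulate(FOPDT(tau=10.5), np.ones(10), dt=1.0)


class TestPIDStep:
    def test_zero_error_zero_output(self):
        state = PIDState(prev_meas=0.0)
        for _ in range(5):
            u, state = pid_step(PIDGains(1.0, 0.5, 0.2), 0.0, 0.0, state, 1.0)
            assert u == 0.0

    def test_proportional_only(self):
        u, _ = pid_step(PIDGains(0.3, 0.0, 0.0), 2.0, 0.0,
                        PIDState(prev_meas=0.0), 1.0)
        assert u == pytest.approx(0.6)

    def test_integral_accumulation_three_steps(self):
        gains = PIDGains(0.0, 0.07, 0.0)
        state = PIDState(prev_meas=0.0)
        for _ in range(3):
            u, state = pid_step(gains, 1.0, 0.0, state, 1.0)
        assert state.integral == pytest.approx(3.0)
        assert u == pytest.approx(3.0 * 0.07)

    def test_derivative_acts_on_measurement_not_error(self):
        gains = PIDGains(0.0, 0.0, 1.0)
        state = PIDState(prev_meas=0.0)
        # setpoint jumps, measurement constant: no derivative kick
        u, state = pid_step(gains, 10.0, 0.0, state, 1.0)
        assert u == 0.0
        # measurement rises: negative derivative
        u, state = pid_step(gains, 10.0, 2.0, state, 1.0)
        assert u == pytest.approx(-2.0)

    def test_anti_windup_holds_integral_at_saturation(self):
        gains = PIDGains(0.0, 1.0, 0.0)
        state = PIDState(prev_meas=0.0)
        for _ in range(50):
            u, state = pid_step(gains, 1.0, 0.0, state, 1.0, u_min=0.0, u_max=1.0)
        assert u == 1.0
        assert state.integral <= 1.0 + 1e-12


class TestDelayLine:
    def test_exact_sample_delay(self):
        line = DelayLine(3, fill=-1.0)
        out = []
        for k in range(8):
            out.append(line.read())
            line.push(float(k))
        assert out == [-1.0, -1.0, -1.0, -1.0, 0.0, 1.0, 2.0, 3.0]

    def test_zero_delay_passthrough_after_push(self):
        line = DelayLine(0, fill=5.0)
        assert line.read() == 5.0
        line.push(7.0)
        assert line.read() == 7.0


class TestZieglerNichols:
    def test_benchmark_plant_matches_frequency_oracle(self):
        plant = FOPDT(A=0.25, B=0.1, tau=10.0)
        zn = zn_ultimate_gain(plant)
        Ku, Tu = ultimate_gain_oracle(plant)
        assert zn.Ku == pytest.approx(Ku, rel=0.02)
        assert zn.Tu == pytest.approx(Tu, rel=0.02)

    @pytest.mark.parametrize("A,B,tau", [
        (0.5, 0.05, 5.0),
        (1.5, 0.2, 3.0),
        (0.1, 0.02, 20.0),
    ])
    def test_random_stable_plants_within_two_percent(self, A, B, tau):
        plant = FOPDT(A=A, B=B, tau=tau)
        zn = zn_ultimate_gain(plant)
        Ku, Tu = ultimate_gain_oracle(plant)
        assert zn.Ku == pytest.approx(Ku, rel=0.02)
        assert zn.Tu == pytest.approx(Tu, rel=0.02)

    def test_delay_free_plant_has_no_ultimate_gain(self):
        with pytest.raises(ValueError, match="ultimate gain"):
            zn_ultimate_gain(FOPDT(tau=0.0))

    def test_gain_scaling(self):
        z1 = zn_ultimate_gain(FOPDT(A=0.25, B=0.1, tau=10.0))
        z2 = zn_ultimate_gain(FOPDT(A=0.5, B=0.1, tau=10.0))
        assert z2.Ku == pytest.approx(z1.Ku / 2.0, rel=0.01)

    def test_classic_table(self):
        gains = zn_initial_gains(ZNResult(Ku=1.0, Tu=8.0))
        assert gains == PIDGains(0.6, 0.15, 0.6)

    def test_published_presets(self):
        assert PID_PRESETS["published_initial"] == PIDGains(0.06, 0.004, 0.45)
        assert PID_PRESETS["published_final"] == PIDGains(0.0015, 0.0005, 0.01)


class TestSimulatedAnnealing:
    def _scenario(self):
        return np.repeat([4.0, 6.5], 300)

    def test_zero_iterations_returns_initial(self):
        plant = FOPDT()
        cfg = SAConfig(iterations=0, seed=0)
        gains, trace = sa_tune_pid(plant, self._scenario(), cfg,
                                   PID_PRESETS["published_initial"])
        assert gains == PID_PRESETS["published_initial"]
        assert len(trace) == 1

    def test_seed_determinism(self):
        plant = FOPDT()
        cfg = SAConfig(iterations=60, seed=42)
        g1, t1 = sa_tune_pid(plant, self._scenario(), cfg,
                             PID_PRESETS["published_initial"])
        g2, t2 = sa_tune_pid(plant, self._scenario(), cfg,
                             PID_PRESETS["published_initial"])
        assert g1 == g2
        assert t1 == t2

    def test_never_worse_than_initial(self):
        plant = FOPDT()
        r = self._scenario()
        cfg = SAConfig(iterations=120, seed=7)
        initial = PID_PRESETS["published_initial"]
        tuned, _ = sa_tune_pid(plant, r, cfg, initial)

        def ise(g):
            y, _ = closed_loop_fopdt(plant, g, r)
            return float(np.sum((r - y) ** 2))

        assert ise(tuned) <= ise(initial)


class TestStabilityBands:
    @pytest.mark.parametrize("target,expected", [
        (4.0, 0.60),
        (6.5, 1.00),
        (15.0, 1.50),
        (20.0, 2.00),
        (30.0, 2.50),
        (35.0, 3.00),
        (5.42, 1.00),   # boundary belongs to the band it opens
        (36.11, 3.00),  # top boundary belongs to the last band
        (0.0, 0.60),
    ])
    def test_lookup(self, target, expected):
        assert critical_band(target) == expected

    @pytest.mark.parametrize("target", [-0.1, 40.0])
    def test_out_of_range_rejected(self, target):
        with pytest.raises(ValueError):
            critical_band(target)

    def test_non_contiguous_rows_rejected(self):
        with pytest.raises(ValueError):
            StabilityBands(rows=((0.0, 5.0, 0.5), (6.0, 10.0, 1.0)))

    def test_decreasing_critical_rejected(self):
        with pytest.raises(ValueError):
            StabilityBands(rows=((0.0, 5.0, 1.0), (5.0, 10.0, 0.5)))


class TestPredictInjection:
    def test_within_margin_needs_no_injection(self, rp, sat):
        plan = predict_injection(TankState(6.45, 6.45), 6.5, rp, sat)
        assert plan.t1 == 0.0

    def test_unreachable_target_rejected(self, rp, sat):
        with pytest.raises(ValueError, match="saturation"):
            predict_injection(TankState(0.0, 0.0), 40.0, rp, sat)

    def test_duration_monotone_in_deficit(self, rp, sat):
        t1s = [
            predict_injection(TankState(c0, c0), 6.5, rp, sat).t1
            for c0 in (5.0, 3.0, 1.0, 0.0)
        ]
        assert all(b >= a for a, b in zip(t1s, t1s[1:]))

    def test_bisection_equals_exhaustive_grid(self, rp, sat):
        cfg = DPPCConfig(t1_max=400.0)
        target, state = 4.0, TankState(0.0, 0.0)
        plan = predict_injection(state, target, rp, sat, cfg)

        # independent exhaustive scan over the 1 s grid
        from duotank.control import _tank_rk4

        margin = cfg.margin * target
        phi_hold = target / 36.1053

        def extremum(t1):
            cj, cy = state.CJ, state.CY
            ext = cy
            for k in range(int(t1)):
                cj, cy = _tank_rk4(cj, cy, 1.0, rp, sat, 1.0)
                ext = max(ext, cy)
            for _ in range(int(cfg.coast_window)):
                cj, cy = _tank_rk4(cj, cy, phi_hold, rp, sat, 1.0)
                ext = max(ext, cy)
            return ext

        grid_minimal = next(
            t1 for t1 in range(0, 401) if extremum(t1) >= target - margin
        )
        while grid_minimal > 0 and extremum(grid_minimal) > target + margin:
            grid_minimal -= 1
        assert plan.t1 == grid_minimal
        assert extremum(plan.t1) >= target - margin
        assert extremum(plan.t1) <= target + margin
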