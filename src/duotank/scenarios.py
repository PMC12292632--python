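"""Closed-loop scenario running and benchmark schedules.

Two plants can be driven:

``fopdt``
    The reduced delay plant A/(s+B) e^(-tau s) at 1 s sampling.  Its input
    is the abstract control variable of the reduced model and is not
    limited to a gas fraction.
``dual_tank``
    The two-zone recirculation ODE; the input is the oxygen volume
    fraction phi in [0, 1] and the measured variable is the growth-zone DO
    seen through the sensor dead time.

Controllers: plain PID feedback, or the hybrid DPPC supervisor.  The
multi-target benchmark schedule steps the DO target through
0 -> 4.0 -> 6.5 -> 9.0 -> 6.5 -> 4.0 mg/L, 600 s per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .control import (
    DEFAULT_BANDS,
    DelayLine,
    DPPCConfig,
    DPPCController,
    FOPDT,
    FOPDTPlanner,
    PID_PRESETS,
    PIDGains,
    PIDState,
    SingleZonePlanner,
    StabilityBands,
    TwoTankPlanner,
    _tank_rk4,
    pid_step,
)
from .metrics import control_metrics
from .tanks import GrowthParams, RecircParams, TankState, Trajectory
from .transfer import PowerLawTransfer, SaturationLaw, csat, kla_power_law

__all__ = [
    "Scenario",
    "BENCHMARK_STAGES",
    "run_scenario",
    "settling_sweep",
    "growth_regulation_run",
    "GrowthRunResult",
]

#: The rapid-target-shift benchmark: (target mg/L, duration s) stages.
BENCHMARK_STAGES = (
    (4.0, 600.0),
    (6.5, 600.0),
    (9.0, 600.0),
    (6.5, 600.0),
    (4.0, 600.0),
)


@dataclass(frozen=True)
class Scenario:
    """A tracking experiment: staged targets from a given initial DO."""

    stages: tuple = BENCHMARK_STAGES
    initial: float = 0.0
    plant: str = "fopdt"
    measurement_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages or any(d <= 0 for _, d in self.stages):
            raise ValueError("stage durations must be positive")
        for target, _ in self.stages:
            if not DEFAULT_BANDS.lower <= target <= DEFAULT_BANDS.upper:
                raise ValueError(f"target {target} outside the band table")
        if self.plant not in ("fopdt", "dual_tank"):
            raise ValueError(f"unknown plant {self.plant!r}")

    def setpoints(self, dt: float = 1.0) -> np.ndarray:
        return np.concatenate(
            [np.full(int(round(d / dt)), tgt) for tgt, d in self.stages]
        )


def run_scenario(
    scenario: Scenario,
    controller: str = "pid",
    gains: PIDGains = PID_PRESETS["published_final"],
    plant_model: FOPDT = FOPDT(),
    rp: RecircParams = RecircParams(),
    sat: SaturationLaw = SaturationLaw(),
    bands: StabilityBands = DEFAULT_BANDS,
    dppc: DPPCConfig = DPPCConfig(),
    dt: float = 1.0,
    sensor_delay: float = 10.0,
) -> tuple:
    """Run one closed-loop scenario; returns (Trajectory, stages, aggregate).

    Deterministic for a fixed scenario seed.  For the dual-tank plant the
    sensor delay applies to the growth-zone DO; for the FOPDT plant the
    plant's own dead time is the sensor delay.
    """
    if controller not in ("pid", "dppc"):
        raise ValueError(f"unknown controller {controller!r}")
    r = scenario.setpoints(dt)
    n = len(r)
    rng = np.random.default_rng(scenario.seed)
    noise = (
        rng.normal(0.0, scenario.measurement_noise_sd, size=n)
        if scenario.measurement_noise_sd > 0
        else np.zeros(n)
    )
    y = np.empty(n)
    us = np.empty(n)
    meas_arr = np.empty(n)
    cj_arr = np.full(n, np.nan)

    if scenario.plant == "fopdt":
        alpha, d = plant_model.discrete(dt)
        gain = plant_model.dc_gain
        x = scenario.initial
        line = DelayLine(d, fill=x)
        if controller == "dppc":
            planner = FOPDTPlanner(plant_model, dppc, sat=sat)
            ctrl = DPPCController(planner, gains, bands, dppc,
                                  u_min=-math.inf, u_max=math.inf)
        else:
            state = PIDState(prev_meas=x)
        for k in range(n):
            m = line.read() + noise[k]
            if controller == "dppc":
                u = ctrl.step(m, r[k], k * dt)
            else:
                u, state = pid_step(gains, r[k], m, state, dt)
            x = alpha * x + (1 - alpha) * gain * u
            line.push(x)
            y[k] = x
            us[k] = u
            meas_arr[k] = m
        phi = np.full(n, np.nan)
    else:
        d = int(round(sensor_delay / dt))
        cj = cy = scenario.initial
        line = DelayLine(d, fill=cy)
        if controller == "dppc":
            planner = TwoTankPlanner(rp, sat, dppc, TankState(cj, cy))
            ctrl = DPPCController(planner, gains, bands, dppc, u_min=0.0, u_max=1.0)
        else:
            state = PIDState(prev_meas=cy)
        for k in range(n):
            m = line.read() + noise[k]
            if controller == "dppc":
                u = ctrl.step(m, r[k], k * dt)
            else:
                u, state = pid_step(gains, r[k], m, state, dt,
                                    u_min=0.0, u_max=1.0)
            cj, cy = _tank_rk4(cj, cy, u, rp, sat, dt)
            line.push(cy)
            y[k] = cy
            cj_arr[k] = cj
            us[k] = u
            meas_arr[k] = m
        phi = us.copy()

    time = np.arange(n) * dt
    traj = Trajectory(
        time=time,
        CJ=cj_arr,
        CY=y,
        phi=phi,
        setpoint=r.astype(float),
        u=us,
        measured=meas_arr,
    )
    stages, agg = control_metrics(time, y, scenario.stages,
                                  initial_level=scenario.initial)
    return traj, stages, agg


def settling_sweep(
    targets: Sequence[float] = (4.0, 6.5, 9.0),
    initials: Sequence[float] = tuple(float(v) for v in range(9)),
    duration: float = 900.0,
    controller: str = "dppc",
    plant: str = "dual_tank",
    **kwargs,
) -> tuple:
    """Settling-time sweep over initial DO x target grids.

    Runs one single-target scenario per (initial, target) pair and collects
    the 5%-band settling time.  Returns (records, mean settling time in s);
    unsettled runs enter the records with NaN and are excluded from the
    mean.
    """
    records = []
    times = []
    for target in targets:
        for initial in initials:
            sc = Scenario(stages=((float(target), duration),),
                          initial=float(initial), plant=plant)
            _, stages, _ = run_scenario(sc, controller=controller, **kwargs)
            st = stages[0]
            records.append(
                {
                    "initial": float(initial),
                    "target": float(target),
                    "settling_time_s": st.settling_time,
                    "overshoot_pct": st.overshoot_pct,
                    "settled": st.settled,
                }
            )
            if st.settled:
                times.append(st.settling_time)
    mean = float(np.mean(times)) if times else math.nan
    return records, mean


@dataclass
class GrowthRunResult:
    """Summary of a growth-coupled regulation run."""

    trajectory: Trajectory
    max_deviation: float
    fluctuation_range: float
    stability_factor: float
    mean_do: float
    final_cells: float
    clamp_events: int


def growth_regulation_run(
    gp: GrowthParams = GrowthParams(),
    target: float = 6.5,
    days: float = 15.0,
    seed: int = 0,
    gains: PIDGains = PID_PRESETS["published_final"],
    transfer: PowerLawTransfer = PowerLawTransfer(),
    sat: SaturationLaw = SaturationLaw(),
    bands: StabilityBands = DEFAULT_BANDS,
    dppc: DPPCConfig = DPPCConfig(),
    dt: float = 1.0,
    sensor_delay: float = 10.0,
    transient: float = 3600.0,
    disturbance_amplitude: float = 0.1,
    store_every: int = 60,
    initial_do: Optional[float] = None,
) -> GrowthRunResult:
    """Closed-loop DPPC regulation of a growing culture.

    The growth-zone DO follows the gassing balance minus Monod uptake of a
    logistically growing cell population; the uptake is perturbed each
    second by a seeded multiplicative uniform(-amplitude, +amplitude)
    factor.  The supervisor holds the DO at ``target`` while the oxygen
    demand rises with the culture.  Post-transient deviation statistics are
    accumulated at full resolution; the returned trajectory is decimated to
    every ``store_every`` samples.
    """
    n = int(round(days * 86400.0 / dt))
    rng = np.random.default_rng(seed)
    c = target if initial_do is None else float(initial_do)
    cell = gp.N0
    d = int(round(sensor_delay / dt))
    line = DelayLine(d, fill=c)

    our_now = [0.0]
    planner = SingleZonePlanner(transfer, sat, dppc, c,
                                our_estimate=lambda: our_now[0])
    ctrl = DPPCController(planner, gains, bands, dppc, u_min=0.0, u_max=1.0)

    keep = np.arange(0, n, store_every)
    times, dos, phis, cells_a, ours_a = (np.empty(len(keep)) for _ in range(5))
    ptr = 0
    maxdev = 0.0
    mn, mx = math.inf, -math.inf
    acc = 0.0
    acc2 = 0.0
    count = 0
    clamps = 0
    n_transient = int(round(transient / dt))
    r, kcap, ourmax, ks, kn = gp.r, gp.K_cap, gp.OURmax, gp.Ks, gp.KN

    for k in range(n):
        m = line.read()
        u = ctrl.step(m, target, k * dt)
        kla = kla_power_law(u, transfer)
        cs = csat(u, sat)
        dist = 1.0 + rng.uniform(-disturbance_amplitude, disturbance_amplitude)

        def f(x, nn):
            our = ourmax * kn * nn * x / (ks + x) * dist
            return kla * (cs - x) - our, r * nn * (1.0 - nn / kcap)

        sub = max(1, int(math.ceil(kla * dt / 0.5)))
        h = dt / sub
        for _ in range(sub):
            k1 = f(c, cell)
            k2 = f(c + 0.5 * h * k1[0], cell + 0.5 * h * k1[1])
            k3 = f(c + 0.5 * h * k2[0], cell + 0.5 * h * k2[1])
            k4 = f(c + h * k3[0], cell + h * k3[1])
            c += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            cell += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if c < 0.0:
            c = 0.0
            clamps += 1
        our_now[0] = ourmax * kn * cell * c / (ks + c)
        line.push(c)
        if ptr < len(keep) and k == keep[ptr]:
            times[ptr] = k * dt
            dos[ptr] = c
            phis[ptr] = u
            cells_a[ptr] = cell
            ours_a[ptr] = our_now[0]
            ptr += 1
        if k >= n_transient:
            dev = abs(c - target)
            if dev > maxdev:
                maxdev = dev
            mn = min(mn, c)
            mx = max(mx, c)
            acc += c
            acc2 += c * c
            count += 1

    mean_do = acc / count if count else math.nan
    std = math.sqrt(max(acc2 / count - mean_do ** 2, 0.0)) if count else math.nan
    traj = Trajectory(
        time=times[:ptr],
        CJ=np.full(ptr, np.nan),
        CY=dos[:ptr],
        phi=phis[:ptr],
        setpoint=np.full(ptr, target),
        u=phis[:ptr],
        N=cells_a[:ptr],
        our=ours_a[:ptr],
        clamp_events=clamps,
    )
    return GrowthRunResult(
        trajectory=traj,
        max_deviation=maxdev,
        fluctuation_range=(mx - mn) if count else math.nan,
        stability_factor=std,
        mean_do=mean_do,
        final_cells=cell,
        clamp_events=clamps,
    )
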