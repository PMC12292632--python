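"""Dissolved-oxygen balances of the dual-tank recirculating system.

Three models are provided, all formulated per second:

``dual_tank``
    Two coupled zones — the aerated/stirred oxygen-enrichment zone (DO
    concentration ``CJ``) and the low-shear cell-growth zone (``CY``) —
    exchanging medium at a volumetric rate V (L/s) relative to the zone
    volume VL (L), each relaxing toward the saturation level C*(phi) with
    its own transfer coefficient (lambda1 for the aerated zone, lambda2 for
    the growth zone)::

        dCJ/dt = (V/VL) (CY - CJ) + lambda1 (C*(phi) - CJ)
        dCY/dt = (V/VL) (CJ - CY) + lambda2 (C*(phi) - CY)

``single_zone``
    First-order gassing dynamics dC/dt = kLa(phi) (C*(phi) - C).

``growth_coupled``
    The single-zone balance minus a Monod-type cellular oxygen uptake,
    with logistic cell growth::

        dN/dt = r N (1 - N/K_cap)
        OUR   = OURmax * KN * N * C / (Ks + C)
        dC/dt = kLa (C* - C) - OUR

Integration is fixed step (RK4 by default, explicit Euler for
cross-checks) over piecewise-constant oxygen-fraction schedules.  States
are clamped at zero after each step; the number of clamps is recorded on
the returned trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .transfer import PowerLawTransfer, SaturationLaw, csat, kla_power_law

__all__ = [
    "TankState",
    "RecircParams",
    "GrowthParams",
    "SimConfig",
    "Trajectory",
    "PiecewiseConstant",
    "SimulationError",
    "dual_tank_rhs",
    "single_zone_rhs",
    "growth_our_rhs",
    "simulate",
]


class SimulationError(RuntimeError):
    """Raised when an integration produces a non-finite state."""


@dataclass
class TankState:
    """DO concentrations (mg/L) in the two zones."""

    CJ: float
    CY: float

    def __post_init__(self) -> None:
        if self.CJ < 0 or self.CY < 0:
            raise ValueError("tank DO concentrations must be >= 0")


@dataclass(frozen=True)
class RecircParams:
    """Recirculation/transfer parameters of the dual-tank model.

    V       : medium exchange flow between the zones, L/s
    VL      : liquid volume of each zone, L
    lambda1 : aerated-zone transfer coefficient, 1/s
    lambda2 : growth-zone transfer coefficient, 1/s
    """

    V: float = 0.3 / 60.0  # 0.3 L/min exchange flow
    VL: float = 3.0
    lambda1: float = 0.0069233
    lambda2: float = 0.0004899

    def __post_init__(self) -> None:
        if self.V < 0 or self.VL <= 0 or self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("invalid recirculation parameters")

    @property
    def exchange_rate(self) -> float:
        """V/VL, 1/s."""
        return self.V / self.VL


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth and Monod oxygen-uptake parameters.

    N0     : initial cell count
    K_cap  : carrying capacity, cells
    r      : logistic growth rate, 1/s
    OURmax : maximal specific uptake scale, mg/(L*s)
    Ks     : Monod half-saturation DO, mg/L
    KN     : per-cell uptake coefficient, 1/cells
    """

    N0: float = 1e7
    K_cap: float = 1e10
    r: float = 1.2e-5
    OURmax: float = 0.5
    Ks: float = 0.5
    KN: float = 1e-11

    def __post_init__(self) -> None:
        if min(self.N0, self.K_cap, self.r, self.OURmax, self.KN) < 0:
            raise ValueError("growth parameters must be >= 0")
        if self.Ks <= 0:
            raise ValueError("Ks must be > 0")
        if not self.K_cap >= self.N0 > 0:
            raise ValueError("need K_cap >= N0 > 0")


@dataclass(frozen=True)
class SimConfig:
    """Fixed-step integration settings (dt and horizon in seconds)."""

    dt: float = 1.0
    horizon: float = 600.0
    seed: int = 0
    method: str = "rk4"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.horizon < self.dt:
            raise ValueError("horizon must be >= dt")
        if self.method not in ("rk4", "euler"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class Trajectory:
    """Time-indexed record of a closed- or open-loop simulation.

    All arrays share one length; ``time`` increases with a constant step.
    Optional channels that do not apply to a model are NaN-filled.
    """

    time: np.ndarray
    CJ: np.ndarray
    CY: np.ndarray
    phi: np.ndarray
    setpoint: Optional[np.ndarray] = None
    u: Optional[np.ndarray] = None
    measured: Optional[np.ndarray] = None
    N: Optional[np.ndarray] = None
    our: Optional[np.ndarray] = None
    clamp_events: int = 0

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("CJ", "CY", "phi", "setpoint", "u", "measured", "N", "our"):
            arr = getattr(self, name)
            if arr is None:
                setattr(self, name, np.full(n, np.nan))
            elif len(arr) != n:
                raise ValueError(f"Trajectory.{name} length mismatch")
        dt = np.diff(self.time)
        if n > 1 and (dt.min() <= 0 or not np.allclose(dt, dt[0])):
            raise ValueError("Trajectory.time must increase with constant step")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self) > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "setpoint": self.setpoint,
                "u": self.u,
                "phi": self.phi,
                "CJ": self.CJ,
                "CY": self.CY,
                "measured": self.measured,
                "N": self.N,
                "our": self.our,
            }
        )


class PiecewiseConstant:
    """Piecewise-constant input schedule u(t).

    Defined by breakpoints ``t_0 = 0 < t_1 < ...`` and values held on
    ``[t_i, t_{i+1})``; the last value extends to ``t_end``.
    """

    def __init__(self, times: Sequence[float], values: Sequence[float],
                 t_end: float = np.inf):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if len(times) != len(values) or len(times) == 0:
            raise ValueError("times and values must have equal nonzero length")
        if times[0] > 0:
            raise ValueError("schedule must start at t = 0 (gap before first value)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("schedule breakpoints must be strictly increasing")
        self.times, self.values, self.t_end = times, values, float(t_end)

    @classmethod
    def constant(cls, value: float) -> "PiecewiseConstant":
        return cls([0.0], [value])

    @classmethod
    def stages(cls, pairs: Iterable[tuple]) -> "PiecewiseConstant":
        """Build from (value, duration) pairs."""
        times, values, t = [], [], 0.0
        for value, duration in pairs:
            times.append(t)
            values.append(value)
            t += duration
        return cls(times, values, t_end=t)

    def __call__(self, t: float) -> float:
        if t < 0 or t > self.t_end:
            raise ValueError(f"schedule does not cover t = {t}")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.values[idx])


def dual_tank_rhs(
    state: TankState,
    phi: float,
    rp: RecircParams = RecircParams(),
    sat: SaturationLaw = SaturationLaw(),
) -> tuple:
    """Right-hand side of the two-zone recirculation balance, mg/L/s."""
    cs = csat(phi, sat)
    k = rp.exchange_rate
    dcj = k * (state.CY - state.CJ) + rp.lambda1 * (cs - state.CJ)
    dcy = k * (state.CJ - state.CY) + rp.lambda2 * (cs - state.CY)
    return dcj, dcy


def single_zone_rhs(
    C: float,
    phi: float,
    law: PowerLawTransfer = PowerLawTransfer(),
    sat: SaturationLaw = SaturationLaw(),
) -> float:
    """Gassing dynamics kLa(phi) * (C*(phi) - C), mg/L/s."""
    return kla_power_law(phi, law) * (csat(phi, sat) - C)


def growth_our_rhs(
    C: float,
    N: float,
    gp: GrowthParams,
    kla: float,
    cstar: float,
) -> tuple:
    """Growth-coupled DO balance; returns (dC/dt, dN/dt, OUR).

    The oxygen uptake rate couples the cell count through the per-cell
    coefficient KN and saturates in DO through the Monod factor:
    OUR = OURmax * KN * N * C / (Ks + C).
    """
    our = gp.OURmax * gp.KN * N * C / (gp.Ks + C)
    dn = gp.r * N * (1.0 - N / gp.K_cap)
    dc = kla * (cstar - C) - our
    return dc, dn, our


def _step(rhs: Callable, y: np.ndarray, dt: float, method: str) -> np.ndarray:
    if method == "euler":
        return y + dt * rhs(y)
    k1 = rhs(y)
    k2 = rhs(y + 0.5 * dt * k1)
    k3 = rhs(y + 0.5 * dt * k2)
    k4 = rhs(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate(
    model: str,
    initial,
    schedule: PiecewiseConstant,
    cfg: SimConfig,
    *,
    transfer: PowerLawTransfer = PowerLawTransfer(),
    sat: SaturationLaw = SaturationLaw(),
    rp: RecircParams = RecircParams(),
    gp: Optional[GrowthParams] = None,
) -> Trajectory:
    """Integrate one of the DO models over a piecewise-constant phi schedule.

    Parameters
    ----------
    model : {"dual_tank", "single_zone", "growth_coupled"}
    initial : TankState for dual_tank, DO in mg/L for single_zone, or
        (DO, N) for growth_coupled (N defaults to ``gp.N0``).
    schedule : phi(t) covering [0, horizon].
    """
    if model not in ("dual_tank", "single_zone", "growth_coupled"):
        raise ValueError(f"unknown model {model!r}")
    n = int(round(cfg.horizon / cfg.dt))
    if schedule.t_end < cfg.horizon:
        raise ValueError("schedule does not cover the simulation horizon")
    time = np.arange(n + 1) * cfg.dt
    phis = np.empty(n + 1)
    clamps = 0

    if model == "dual_tank":
        state = np.array([initial.CJ, initial.CY], dtype=float)
    elif model == "single_zone":
        state = np.array([float(initial)], dtype=float)
    else:
        gp = gp or GrowthParams()
        if np.ndim(initial) == 0:
            state = np.array([float(initial), gp.N0])
        else:
            state = np.asarray(initial, dtype=float).copy()

    out = np.empty((n + 1, len(state)))
    ours = np.full(n + 1, np.nan)
    out[0] = state
    phis[0] = schedule(0.0)
    if model == "growth_coupled":
        kla0 = kla_power_law(phis[0], transfer)
        ours[0] = growth_our_rhs(state[0], state[1], gp, kla0, csat(phis[0], sat))[2]

    for k in range(n):
        phi = schedule(k * cfg.dt)
        if model == "dual_tank":
            cs = csat(phi, sat)
            kx = rp.exchange_rate

            def rhs(y, cs=cs, kx=kx):
                return np.array(
                    [
                        kx * (y[1] - y[0]) + rp.lambda1 * (cs - y[0]),
                        kx * (y[0] - y[1]) + rp.lambda2 * (cs - y[1]),
                    ]
                )

        elif model == "single_zone":
            kla = kla_power_law(phi, transfer)
            cs = csat(phi, sat)

            def rhs(y, kla=kla, cs=cs):
                return np.array([kla * (cs - y[0])])

        else:
            kla = kla_power_law(phi, transfer)
            cs = csat(phi, sat)

            def rhs(y, kla=kla, cs=cs):
                dc, dn, _ = growth_our_rhs(y[0], y[1], gp, kla, cs)
                return np.array([dc, dn])

        state = _step(rhs, state, cfg.dt, cfg.method)
        if not np.all(np.isfinite(state)):
            raise SimulationError(f"non-finite state at step {k + 1}")
        if state.min() < 0.0:
            clamps += 1
            state = np.clip(state, 0.0, None)
        out[k + 1] = state
        phis[k + 1] = phi
        if model == "growth_coupled":
            ours[k + 1] = growth_our_rhs(state[0], state[1], gp, kla, cs)[2]

    if model == "dual_tank":
        cj, cy, ncol = out[:, 0], out[:, 1], None
    elif model == "single_zone":
        cj = np.full(n + 1, np.nan)
        cy, ncol = out[:, 0], None
    else:
        cj = np.full(n + 1, np.nan)
        cy, ncol = out[:, 0], out[:, 1]
    return Trajectory(
        time=time, CJ=cj, CY=cy, phi=phis, N=ncol, our=ours, clamp_events=clamps
    )
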