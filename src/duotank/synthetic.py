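"""Synthetic DO data with known ground truth.

Emulates the three identification experiments of the reference system:

* ``gassing_out`` — the exponential DO rise after nitrogen stripping at a
  fixed oxygen fraction (single-zone transfer dynamics);
* ``dual_tank`` — paired zone traces of the recirculation model under a
  phi schedule;
* ``saturation_points`` — replicate saturated-DO measurements across a set
  of oxygen fractions.

Noise is additive Gaussian on the DO values, seeded; a noise standard
deviation of zero reproduces the exact model curves, so every estimator
can be validated by round-trip recovery.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .identify import DOTrace
from .tanks import (
    PiecewiseConstant,
    RecircParams,
    SimConfig,
    TankState,
    simulate,
)
from .transfer import SaturationLaw, csat

__all__ = ["generate_synthetic_trace"]


def generate_synthetic_trace(
    kind: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    # gassing_out
    kla: float = 0.02,
    cstar: float = 7.58,
    c0: float = 0.0,
    duration: float = 300.0,
    dt: float = 1.0,
    phi: float = 0.21,
    # dual_tank
    rp: RecircParams = RecircParams(),
    sat: SaturationLaw = SaturationLaw(),
    initial: Optional[TankState] = None,
    phi_schedule: Optional[PiecewiseConstant] = None,
    # saturation_points
    c: float = 36.1053,
    phis: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0),
    replicates: int = 5,
):
    """Generate a synthetic experiment of the requested ``kind``.

    Returns a :class:`DOTrace` for ``gassing_out``, a ``{zone: DOTrace}``
    mapping for ``dual_tank``, and ``(phis, csats)`` with ``csats`` of
    shape (len(phis), replicates) for ``saturation_points``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if kind == "gassing_out":
        t = np.arange(0.0, duration + dt / 2, dt)
        values = cstar + (c0 - cstar) * np.exp(-kla * t)
        values = values + rng.normal(0.0, noise_sd, size=t.shape)
        return DOTrace(time=t, value=values, phi=phi, zone="Y")
    if kind == "dual_tank":
        schedule = phi_schedule or PiecewiseConstant.constant(phi)
        cfg = SimConfig(dt=dt, horizon=duration)
        state = initial or TankState(0.0, 0.0)
        traj = simulate("dual_tank", state, schedule, cfg, sat=sat, rp=rp)
        noise = rng.normal(0.0, noise_sd, size=(2, len(traj.time)))
        phi_arr = traj.phi
        return {
            "J": DOTrace(time=traj.time, value=traj.CJ + noise[0],
                         phi=phi_arr if np.ptp(phi_arr) else float(phi_arr[0]),
                         zone="J"),
            "Y": DOTrace(time=traj.time, value=traj.CY + noise[1],
                         phi=phi_arr if np.ptp(phi_arr) else float(phi_arr[0]),
                         zone="Y"),
        }
    if kind == "saturation_points":
        phis_arr = np.asarray(phis, dtype=float)
        law = SaturationLaw(c=c)
        truth = csat(phis_arr, law)
        csats = truth[:, None] + rng.normal(0.0, noise_sd,
                                            size=(len(phis_arr), replicates))
        return phis_arr, csats
    raise ValueError(f"unknown synthetic kind {kind!r}")
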