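"""Parameter identification from DO time series.

Estimators for every constant of the process model:

* ``estimate_kla`` — dynamic gassing-out: the slope of ln(C* - C(t)) against
  time gives -kLa, using every sample via ordinary least squares (the
  classical two-point formula is the degenerate n = 2 case);
* ``fit_power_law`` — log-log regression of kLa against phi, returned both
  as the direct pair (a, m) and as the dimensionless pair (n1, n2);
* ``fit_saturation`` — the linear Henry-type constant c (least squares
  through the origin) or the thermodynamic constants (d1, d2);
* ``fit_recirc_lambdas`` — nonlinear least squares of the two-zone
  recirculation simulation against paired zone traces;
* ``goodness_of_fit`` — RMSE and R².

Each estimator is exposed twice: as a plain function and as a small
model class (``GassingOutKLa``, ``PowerLawKLa``, ``SaturationModel``,
``RecirculationModel``) whose ``fit()`` returns an
:class:`IdentificationResults` carrying estimates, standard errors,
residual diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .tanks import (
    PiecewiseConstant,
    RecircParams,
    SimConfig,
    TankState,
    simulate,
)
from .transfer import (
    DimensionlessFit,
    PowerLawTransfer,
    SaturationLaw,
    dimensionless_from_power_law,
)

__all__ = [
    "DOTrace",
    "FitReport",
    "IdentificationError",
    "estimate_kla",
    "fit_power_law",
    "fit_saturation",
    "fit_recirc_lambdas",
    "goodness_of_fit",
    "GassingOutKLa",
    "PowerLawKLa",
    "SaturationModel",
    "RecirculationModel",
    "IdentificationResults",
]


class IdentificationError(ValueError):
    """Raised for unidentifiable or out-of-domain identification inputs."""


@dataclass
class DOTrace:
    """A sensor time series: DO (mg/L) against time (s) in one zone."""

    time: np.ndarray
    value: np.ndarray
    phi: float = 0.21
    zone: str = "Y"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.time) != len(self.value) or len(self.time) < 2:
            raise ValueError("DOTrace needs >= 2 paired samples")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.value))):
            raise ValueError("DOTrace contains non-finite values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("DOTrace.time must be strictly increasing")
        if self.zone not in ("J", "Y"):
            raise ValueError("zone must be 'J' or 'Y'")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class FitReport:
    """Estimates with standard errors and residual diagnostics."""

    estimates: dict
    stderr: dict
    residuals: np.ndarray
    rmse: float
    r2: float
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["parameter      estimate      std.err."]
        for k, v in self.estimates.items():
            se = self.stderr.get(k, np.nan)
            lines.append(f"{k:<12} {v:>12.6g} {se:>12.3g}")
        lines.append(f"RMSE = {self.rmse:.6g}   R^2 = {self.r2:.6g}")
        return "\n".join(lines)


def goodness_of_fit(pred, obs) -> tuple:
    """Root-mean-square error and coefficient of determination.

    R² is undefined (NaN, with a warning) when the observations have zero
    variance.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero-variance observations: R^2 undefined", RuntimeWarning)
        return rmse, float("nan")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return rmse, r2


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple:
    """Least-squares line y = b0 + b1 x; returns (b0, b1, se0, se1)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(x) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta[0], beta[1], se[0], se[1]


def estimate_kla(trace: DOTrace, cstar: float) -> tuple:
    """Dynamic gassing-out kLa estimate (1/s) from a DO rise curve.

    Regresses ln(cstar - C(t)) on t over all samples; kLa is the negated
    slope.  Exact on noise-free exponentials and invariant to uniform time
    translation.  Any sample at or above ``cstar`` is a domain error.
    """
    bad = np.nonzero(trace.value >= cstar)[0]
    if bad.size:
        raise IdentificationError(
            f"sample {bad[0]} (t = {trace.time[bad[0]]:g} s) has DO >= cstar; "
            "the gassing-out logarithm is undefined"
        )
    y = np.log(cstar - trace.value)
    b0, b1, _, se1 = _ols_line(trace.time, y)
    kla = -b1
    pred = cstar - np.exp(b0 + b1 * trace.time)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rmse, r2 = goodness_of_fit(pred, trace.value)
    report = FitReport(
        estimates={"kla": kla},
        stderr={"kla": se1},
        residuals=trace.value - pred,
        rmse=rmse,
        r2=r2,
        extra={"n": len(trace), "cstar": cstar},
    )
    return kla, report


def fit_power_law(
    phis: Sequence[float],
    klas: Sequence[float],
    fit: DimensionlessFit = DimensionlessFit(),
) -> tuple:
    """Log-log fit of the transfer power law; returns (law, dimfit, report).

    ``law`` is the direct :class:`PowerLawTransfer` (a, m) from regressing
    ln kLa on ln phi; ``dimfit`` is the equivalent dimensionless pair
    (n1, n2) in the geometry of ``fit``, satisfying m = n2/2 exactly.
    """
    phis = np.asarray(phis, dtype=float)
    klas = np.asarray(klas, dtype=float)
    if np.any(phis <= 0) or np.any(klas <= 0):
        raise IdentificationError("phi and kLa values must be positive")
    if len(np.unique(phis)) < 2:
        raise IdentificationError("need >= 2 distinct phi values")
    b0, b1, se0, se1 = _ols_line(np.log(phis), np.log(klas))
    law = PowerLawTransfer(a=float(np.exp(b0)), m=float(b1))
    dimfit = dimensionless_from_power_law(law, dB=fit.dB, g=fit.g, rho=fit.rho)
    pred = law.a * phis ** law.m
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rmse, r2 = goodness_of_fit(pred, klas)
    report = FitReport(
        estimates={"a": law.a, "m": law.m, "n1": dimfit.n1, "n2": dimfit.n2},
        stderr={"a": law.a * se0, "m": se1},
        residuals=klas - pred,
        rmse=rmse,
        r2=r2,
    )
    return law, dimfit, report


def fit_saturation(
    phis: Sequence[float],
    csats: Sequence[float],
    mode: str = "linear",
    P: float = 101325.0,
    P_H2O: float = 6274.0,
) -> tuple:
    """Fit the saturation law; returns (SaturationLaw, FitReport).

    ``csats`` may be a 1-D vector of per-phi means or a 2-D array of
    replicate measurements (replicates are averaged).  Linear mode is the
    closed-form least-squares slope through the origin; thermo mode fits
    (d1, d2) of the chemical-potential form, which is linear after taking
    logarithms, then refines on the original scale.
    """
    phis = np.asarray(phis, dtype=float)
    csats = np.asarray(csats, dtype=float)
    if csats.ndim == 2:
        csats = csats.mean(axis=1)
    if len(phis) != len(csats):
        raise ValueError("phis and csats must have equal length")
    if mode == "linear":
        # the through-origin slope is identifiable from any nonzero phi
        if np.sum(phis ** 2) == 0.0:
            raise IdentificationError("degenerate design: all phi values zero")
        c = float(np.sum(phis * csats) / np.sum(phis ** 2))
        law = SaturationLaw(c=c, P=P, P_H2O=P_H2O, mode="linear")
        pred = c * phis
        dof = max(len(phis) - 1, 1)
        se = float(
            np.sqrt(np.sum((csats - pred) ** 2) / dof / np.sum(phis ** 2))
        )
        estimates, stderr = {"c": c}, {"c": se}
    elif mode == "thermo":
        if len(phis) < 3:
            raise IdentificationError("need >= 3 points for the thermo law")
        if len(np.unique(phis)) < 2:
            raise IdentificationError("degenerate design: all phi values equal")
        if np.any(phis <= 0) or np.any(csats <= 0):
            raise IdentificationError("thermo fit requires positive phi and C*")
        x = np.log(phis * (P - P_H2O))
        y = np.log(csats / 32e3)
        b0, b1, se0, se1 = _ols_line(x, y)  # y = d1*x - d2

        def resid(p):
            return 32e3 * np.exp(p[0] * x - p[1]) - csats

        sol = least_squares(resid, x0=[b1, -b0], method="lm")
        d1, d2 = sol.x
        law = SaturationLaw(d1=float(d1), d2=float(d2), P=P, P_H2O=P_H2O,
                            mode="thermo")
        pred = 32e3 * np.exp(d1 * x - d2)
        estimates = {"d1": float(d1), "d2": float(d2)}
        stderr = {"d1": se1, "d2": se0}
    else:
        raise ValueError(f"unknown saturation mode {mode!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rmse, r2 = goodness_of_fit(pred, csats)
    return law, FitReport(estimates, stderr, csats - pred, rmse, r2)


def _simulate_pair(lam1, lam2, rp, sat, phi_schedule, time, cj0, cy0):
    cfg = SimConfig(dt=float(time[1] - time[0]), horizon=float(time[-1]))
    rp2 = RecircParams(V=rp.V, VL=rp.VL, lambda1=lam1, lambda2=lam2)
    traj = simulate("dual_tank", TankState(cj0, cy0), phi_schedule, cfg,
                    sat=sat, rp=rp2)
    return traj.CJ, traj.CY


def fit_recirc_lambdas(
    trace_j: DOTrace,
    trace_y: DOTrace,
    rp: RecircParams,
    sat: SaturationLaw,
    phi_schedule: PiecewiseConstant,
) -> tuple:
    """Estimate the zone transfer coefficients (lambda1, lambda2), 1/s.

    Minimises the summed squared deviation between the two-zone simulation
    and both measured traces (equal weights) by least squares in
    log10(lambda) space, started from a deterministic grid over the decades
    1e-4 ... 1e-1.  Traces must share one uniform time grid.  Flat
    (zero-information) traces raise :class:`IdentificationError`.
    """
    if len(trace_j) != len(trace_y) or not np.allclose(trace_j.time, trace_y.time):
        raise ValueError("zone traces must share a common time grid")
    time = trace_j.time
    if not np.allclose(np.diff(time), time[1] - time[0]):
        raise ValueError("lambda fitting requires a uniform time grid")
    if np.ptp(trace_j.value) < 1e-12 and np.ptp(trace_y.value) < 1e-12:
        raise IdentificationError(
            "flat equilibrium traces carry no information about the lambdas"
        )
    obs = np.concatenate([trace_j.value, trace_y.value])
    # sensor noise can push the first sample marginally below zero
    cj0 = max(float(trace_j.value[0]), 0.0)
    cy0 = max(float(trace_y.value[0]), 0.0)

    def resid(logs):
        try:
            cj, cy = _simulate_pair(10.0 ** logs[0], 10.0 ** logs[1], rp, sat,
                                    phi_schedule, time, cj0, cy0)
        except Exception:
            return np.full(2 * len(time), 1e6)
        return np.concatenate([cj, cy]) - obs

    # bounded search in log10 space keeps the fixed-step simulation stable
    bounds = ([-6.0, -6.0], [-0.5, -0.5])
    best = None
    for l1 in (-4.0, -3.0, -2.0, -1.0):
        for l2 in (-4.0, -3.0, -2.0, -1.0):
            sol = least_squares(resid, x0=[l1, l2], method="trf", bounds=bounds)
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise IdentificationError(
            "lambda optimisation failed to converge; best SSE = "
            f"{(2 * best.cost) if best is not None else float('nan'):g}"
        )
    lam1, lam2 = (10.0 ** v for v in best.x)
    r = best.fun
    pred = obs - r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rmse, r2 = goodness_of_fit(pred, obs)
    report = FitReport(
        estimates={"lambda1": lam1, "lambda2": lam2},
        stderr={},
        residuals=r,
        rmse=rmse,
        r2=r2,
        extra={"sse": float(2 * best.cost)},
    )
    return lam1, lam2, report


# ---------------------------------------------------------------------------
# Model/Results presentation layer


@dataclass
class IdentificationResults:
    """Fitted-parameter container shared by the identification models."""

    model: object
    report: FitReport

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.report.estimates)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.report.stderr).reindex(self.report.estimates)

    @property
    def rmse(self) -> float:
        return self.report.rmse

    @property
    def rsquared(self) -> float:
        return self.report.r2

    @property
    def resid(self) -> np.ndarray:
        return self.report.residuals

    def summary(self) -> str:
        head = f"{type(self.model).__name__} results\n"
        return head + self.report.summary()


class GassingOutKLa:
    """Dynamic gassing-out model for a single DO rise curve."""

    def __init__(self, trace: DOTrace, cstar: float):
        self.trace, self.cstar = trace, cstar

    def fit(self) -> IdentificationResults:
        kla, report = estimate_kla(self.trace, self.cstar)
        return IdentificationResults(self, report)


class PowerLawKLa:
    """Power-law transfer model across a set of (phi, kLa) measurements."""

    def __init__(self, phis, klas, geometry: DimensionlessFit = DimensionlessFit()):
        self.phis, self.klas, self.geometry = phis, klas, geometry

    def fit(self) -> IdentificationResults:
        law, dimfit, report = fit_power_law(self.phis, self.klas, self.geometry)
        res = IdentificationResults(self, report)
        res.law, res.dimfit = law, dimfit
        return res


class SaturationModel:
    """Saturated-DO law across (phi, C*) points, linear or thermo mode."""

    def __init__(self, phis, csats, mode: str = "linear", **pressures):
        self.phis, self.csats, self.mode, self.pressures = phis, csats, mode, pressures

    def fit(self) -> IdentificationResults:
        law, report = fit_saturation(self.phis, self.csats, self.mode,
                                     **self.pressures)
        res = IdentificationResults(self, report)
        res.law = law
        return res


class RecirculationModel:
    """Two-zone recirculation model fitted to paired zone traces."""

    def __init__(self, trace_j: DOTrace, trace_y: DOTrace, rp: RecircParams,
                 sat: SaturationLaw, phi_schedule: PiecewiseConstant):
        self.trace_j, self.trace_y = trace_j, trace_y
        self.rp, self.sat, self.phi_schedule = rp, sat, phi_schedule

    def fit(self) -> IdentificationResults:
        lam1, lam2, report = fit_recirc_lambdas(
            self.trace_j, self.trace_y, self.rp, self.sat, self.phi_schedule
        )
        res = IdentificationResults(self, report)
        res.lambdas = (lam1, lam2)
        return res
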