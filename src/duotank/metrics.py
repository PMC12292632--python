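"""Control-performance metrics: ISE, IAE, overshoot, settling time.

Conventions: ISE and IAE are discrete integrals sum(e^2)*dt and
sum(|e|)*dt over the whole run.  Per stage, overshoot is the peak
excursion beyond the target in the direction of the step, as a percent of
the target; settling time is the first instant after which the error stays
within 5% of the target for the remainder of the stage; steady-state error
is the mean |e| over the final 10% of the stage, which is also the window
for the fluctuation range (max - min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ControlMetrics", "StageMetrics", "control_metrics", "compare_controllers"]


@dataclass
class ControlMetrics:
    """Aggregate error metrics of one closed-loop run."""

    ise: float
    iae: float
    overshoot_pct: float
    settling_time: float
    steady_state_error: float
    fluctuation_range: float
    settled: bool = True


@dataclass
class StageMetrics:
    """Per-stage metrics; ``overshoot_pct`` is NaN for a zero target."""

    target: float
    start: float
    duration: float
    ise: float
    iae: float
    overshoot_pct: float
    settling_time: float
    steady_state_error: float
    fluctuation_range: float
    settled: bool


def _stage_metrics(t, y, target, prev_level, dt, band=0.05):
    e = target - y
    ise = float(np.sum(e ** 2) * dt)
    iae = float(np.sum(np.abs(e)) * dt)
    direction = 1.0 if target >= prev_level else -1.0
    if target == 0.0:
        overshoot = math.nan
    elif direction > 0:
        overshoot = max(0.0, float(y.max()) - target) / target * 100.0
    else:
        overshoot = max(0.0, target - float(y.min())) / target * 100.0
    tol = band * abs(target) if target != 0.0 else band
    ok = np.abs(e) <= tol
    settled = False
    settling = math.nan
    # first index from which the error stays inside the band
    bad = np.nonzero(~ok)[0]
    first = 0 if bad.size == 0 else bad[-1] + 1
    if first < len(ok):
        settled = True
        settling = float(t[first] - t[0])
    tail = max(1, int(round(0.1 * len(y))))
    sse = float(np.mean(np.abs(e[-tail:])))
    fluct = float(np.ptp(y[-tail:]))
    return StageMetrics(
        target=target,
        start=float(t[0]),
        duration=float(t[-1] - t[0] + dt),
        ise=ise,
        iae=iae,
        overshoot_pct=overshoot,
        settling_time=settling,
        steady_state_error=sse,
        fluctuation_range=fluct,
        settled=settled,
    )


def control_metrics(
    time: Sequence[float],
    value: Sequence[float],
    stages: Sequence[tuple],
    initial_level: Optional[float] = None,
) -> tuple:
    """Per-stage and aggregate metrics of a tracking run.

    Parameters
    ----------
    time, value : trajectory samples (uniform step).
    stages : ordered (target mg/L, duration s) pairs covering the run.
    initial_level : level before the first stage (defaults to value[0]),
        used to decide the direction of the first step.

    Returns
    -------
    (list of StageMetrics, ControlMetrics)
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(value, dtype=float)
    if len(t) != len(y) or len(t) < 2:
        raise ValueError("time and value must have equal length >= 2")
    dt = float(t[1] - t[0])
    total = sum(d for _, d in stages)
    if total > t[-1] - t[0] + dt * 1.5:
        raise ValueError("trajectory does not cover all stages")
    prev = float(y[0]) if initial_level is None else float(initial_level)
    out = []
    idx = 0
    for target, duration in stages:
        n = int(round(duration / dt))
        sl = slice(idx, min(idx + n, len(t)))
        out.append(_stage_metrics(t[sl], y[sl], target, prev, dt))
        prev = target
        idx += n
    ise = float(sum(s.ise for s in out))
    iae = float(sum(s.iae for s in out))
    overshoots = [s.overshoot_pct for s in out if not math.isnan(s.overshoot_pct)]
    settlings = [s.settling_time for s in out if s.settled]
    agg = ControlMetrics(
        ise=ise,
        iae=iae,
        overshoot_pct=max(overshoots) if overshoots else math.nan,
        settling_time=float(np.mean(settlings)) if settlings else math.nan,
        steady_state_error=float(np.mean([s.steady_state_error for s in out])),
        fluctuation_range=max(s.fluctuation_range for s in out),
        settled=all(s.settled for s in out),
    )
    return out, agg


def compare_controllers(results: dict, stages: Sequence[tuple],
                        baseline: str = "pid") -> pd.DataFrame:
    """Tabulate per-transition overshoot and aggregate ISE/IAE reductions.

    ``results`` maps controller name -> (stage_metrics, aggregate) as
    returned by :func:`control_metrics`.  The reduction columns compare
    each controller against ``baseline`` as (base - x)/base * 100.
    """
    if baseline not in results:
        raise ValueError(f"baseline {baseline!r} missing from results")
    names = list(results)
    rows = []
    prev = None
    base_stages = results[baseline][0]
    for i, (target, _) in enumerate(stages):
        row = {"transition": f"{prev if prev is not None else 0.0:g}-{target:g}"}
        for name in names:
            row[f"overshoot_{name}_pct"] = results[name][0][i].overshoot_pct
        base = base_stages[i].overshoot_pct
        for name in names:
            if name == baseline:
                continue
            x = results[name][0][i].overshoot_pct
            row[f"reduction_{name}_pct"] = (
                math.nan if (math.isnan(base) or base == 0.0)
                else (base - x) / base * 100.0
            )
        rows.append(row)
        prev = target
    frame = pd.DataFrame(rows)
    agg = {"transition": "aggregate"}
    for metric in ("ise", "iae"):
        base = getattr(results[baseline][1], metric)
        for name in names:
            agg[f"{metric}_{name}"] = getattr(results[name][1], metric)
        for name in names:
            if name != baseline and base > 0:
                agg[f"{metric}_reduction_{name}_pct"] = (
                    (base - getattr(results[name][1], metric)) / base * 100.0
                )
    frame.attrs["aggregate"] = agg
    return frame


def format_report(frame: pd.DataFrame) -> str:
    """Aligned-text rendering of a comparison table and its aggregate row."""
    text = frame.to_string(index=False, float_format=lambda v: f"{v:.2f}")
    agg = frame.attrs.get("aggregate")
    if agg:
        text += "\n" + "  ".join(
            f"{k}={v:.2f}" if isinstance(v, float) else f"{k}={v}"
            for k, v in agg.items()
        )
    return text
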