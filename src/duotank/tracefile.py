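"""Plain-text trace and trajectory files.

Sensor traces are CSV with the header ``time_s,zone,do_mg_per_l,phi`` and
zone labels J (aerated) / Y (growth).  Values round-trip at full float
precision.  Percent-style oxygen fractions (values above 1) are divided by
100 on read, with a warning — fractions stay 0-1 inside the library.
Closed-loop trajectories use the header
``time_s,setpoint,u,phi,CJ,CY,measured,N,our``.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .identify import DOTrace
from .tanks import Trajectory

__all__ = ["read_trace", "write_trace", "read_trajectory", "write_trajectory"]

TRACE_HEADER = ["time_s", "zone", "do_mg_per_l", "phi"]
TRAJ_HEADER = ["time_s", "setpoint", "u", "phi", "CJ", "CY", "measured", "N", "our"]


def write_trace(path, traces: Union[DOTrace, Dict[str, DOTrace]]) -> None:
    """Write one trace or a {zone: trace} mapping as CSV."""
    if isinstance(traces, DOTrace):
        traces = {traces.zone: traces}
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRACE_HEADER)
        for zone in sorted(traces):
            tr = traces[zone]
            phi = np.broadcast_to(np.asarray(tr.phi, dtype=float), tr.time.shape)
            for t, v, p in zip(tr.time, tr.value, phi):
                w.writerow([repr(float(t)), zone, repr(float(v)), repr(float(p))])


def read_trace(path) -> Dict[str, DOTrace]:
    """Read a trace CSV into a {zone: DOTrace} mapping.

    Raises ValueError naming the offending column or line for malformed
    headers, non-numeric cells and non-increasing timestamps.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty trace file")
    header = [h.strip() for h in rows[0]]
    if header != TRACE_HEADER:
        missing = [c for c in TRACE_HEADER if c not in header]
        bogus = [c for c in header if c not in TRACE_HEADER]
        raise ValueError(
            f"{path}: bad header; missing column(s) {missing}, "
            f"unexpected {bogus}"
        )
    data: Dict[str, dict] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 cells")
        t_s, zone, do_s, phi_s = (cell.strip() for cell in row)
        try:
            t, do, phi = float(t_s), float(do_s), float(phi_s)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric cell") from exc
        rec = data.setdefault(zone, {"time": [], "value": [], "phi": [], "line": []})
        if rec["time"] and t <= rec["time"][-1]:
            raise ValueError(
                f"{path}: line {lineno}: time not strictly increasing "
                f"(row {lineno - 1} of the file)"
            )
        rec["time"].append(t)
        rec["value"].append(do)
        rec["phi"].append(phi)
    out: Dict[str, DOTrace] = {}
    for zone, rec in data.items():
        phi = np.asarray(rec["phi"], dtype=float)
        if np.any(phi > 1.0):
            warnings.warn(
                f"{path}: zone {zone}: phi column looks percent-style; "
                "dividing by 100",
                UserWarning,
            )
            phi = phi / 100.0
        phi_val = float(phi[0]) if np.ptp(phi) == 0 else phi
        out[zone] = DOTrace(
            time=np.asarray(rec["time"]),
            value=np.asarray(rec["value"]),
            phi=phi_val,
            zone=zone,
        )
    return out


def write_trajectory(path, traj: Trajectory) -> None:
    frame = traj.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns) != TRAJ_HEADER:
        raise ValueError(f"{path}: bad trajectory header {list(frame.columns)}")
    return Trajectory(
        time=frame["time_s"].to_numpy(),
        CJ=frame["CJ"].to_numpy(),
        CY=frame["CY"].to_numpy(),
        phi=frame["phi"].to_numpy(),
        setpoint=frame["setpoint"].to_numpy(),
        u=frame["u"].to_numpy(),
        measured=frame["measured"].to_numpy(),
        N=frame["N"].to_numpy(),
        our=frame["our"].to_numpy(),
    )
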