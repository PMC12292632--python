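"""Configuration: every model constant in one serialisable tree.

Defaults are the fitted constants of the reference 3 L dual-tank system.
Files may be YAML or JSON; unknown keys are rejected by name, and a loaded
tree round-trips through serialisation unchanged.  The recirculation
exchange flow is configured per minute (as operators specify it) and
converted to per-second units at this boundary.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .control import (
    DEFAULT_BANDS,
    DPPCConfig,
    FOPDT,
    PIDGains,
    StabilityBands,
)
from .tanks import GrowthParams, RecircParams
from .transfer import DimensionlessFit, PowerLawTransfer, SaturationLaw

__all__ = [
    "DEFAULTS",
    "load_config",
    "save_config",
    "config_hash",
    "transfer_from_config",
    "dimensionless_from_config",
    "saturation_from_config",
    "recirc_from_config",
    "growth_from_config",
    "plant_from_config",
    "gains_from_config",
    "bands_from_config",
    "dppc_from_config",
]

DEFAULTS = {
    "transfer": {"a": 2.5302, "m": 1.9139},
    "dimensionless": {
        "n1": 3.23e-6,
        "n2": 3.8278,
        "dB_m": 0.128,
        "g_m_per_s2": 9.0866,
        "rho_kg_per_m3": 1250.0,
    },
    "saturation": {
        "c": 36.1053,
        "d1": 0.0022,
        "d2": 4.6525,
        "P_pa": 101325.0,
        "P_H2O_pa": 6274.0,
        "mode": "linear",
    },
    "recirculation": {
        "V_l_per_min": 0.3,
        "VL_l": 3.0,
        "lambda1": 0.0069233,
        "lambda2": 0.0004899,
    },
    "growth": {
        "N0": 1e7,
        "K_cap": 1e10,
        "r_per_s": 1.2e-5,
        "OURmax": 0.5,
        "Ks": 0.5,
        "KN": 1e-11,
    },
    "plant": {"A": 0.25, "B": 0.1, "tau_s": 10.0},
    "pid": {
        "published_initial": {"Kp": 0.06, "Ki": 0.004, "Kd": 0.45},
        "published_final": {"Kp": 0.0015, "Ki": 0.0005, "Kd": 0.01},
        "Ku": 0.1247,
        "Tu_s": 30.0,
    },
    "bands": [list(row) for row in DEFAULT_BANDS.rows],
    "dppc": {
        "margin": 0.05,
        "injection_phi": 1.0,
        "replan_interval_s": 30.0,
        "dt_s": 1.0,
        "coast_window_s": 300.0,
        "t1_max_s": 900.0,
    },
}


def _check_keys(tree, reference, path=""):
    if isinstance(reference, dict):
        if not isinstance(tree, dict):
            raise ValueError(f"config section {path or '<root>'} must be a mapping")
        for key in tree:
            if key not in reference:
                raise ValueError(f"unknown config key: {path + key!r}")
            _check_keys(tree[key], reference[key], path + key + ".")


def _merge(base, override):
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Load a YAML/JSON config merged over the defaults.

    ``path=None`` returns a deep copy of :data:`DEFAULTS`.  Unknown keys
    raise ValueError naming the offending key.
    """
    if path is None:
        return copy.deepcopy(DEFAULTS)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    tree = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    ) or {}
    _check_keys(tree, DEFAULTS)
    return _merge(DEFAULTS, tree)


def save_config(cfg: dict, path) -> None:
    """Write the config as YAML or JSON depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config tree (for provenance logs)."""
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def transfer_from_config(cfg: dict) -> PowerLawTransfer:
    t = cfg["transfer"]
    return PowerLawTransfer(a=t["a"], m=t["m"])


def dimensionless_from_config(cfg: dict) -> DimensionlessFit:
    d = cfg["dimensionless"]
    return DimensionlessFit(
        n1=d["n1"], n2=d["n2"], dB=d["dB_m"], g=d["g_m_per_s2"],
        rho=d["rho_kg_per_m3"],
    )


def saturation_from_config(cfg: dict) -> SaturationLaw:
    s = cfg["saturation"]
    return SaturationLaw(
        c=s["c"], d1=s["d1"], d2=s["d2"], P=s["P_pa"], P_H2O=s["P_H2O_pa"],
        mode=s["mode"],
    )


def recirc_from_config(cfg: dict) -> RecircParams:
    r = cfg["recirculation"]
    return RecircParams(
        V=r["V_l_per_min"] / 60.0,  # per-minute flow -> per-second
        VL=r["VL_l"],
        lambda1=r["lambda1"],
        lambda2=r["lambda2"],
    )


def growth_from_config(cfg: dict) -> GrowthParams:
    g = cfg["growth"]
    return GrowthParams(
        N0=g["N0"], K_cap=g["K_cap"], r=g["r_per_s"], OURmax=g["OURmax"],
        Ks=g["Ks"], KN=g["KN"],
    )


def plant_from_config(cfg: dict) -> FOPDT:
    p = cfg["plant"]
    return FOPDT(A=p["A"], B=p["B"], tau=p["tau_s"])


def gains_from_config(cfg: dict, preset: str = "published_final") -> PIDGains:
    g = cfg["pid"][preset]
    return PIDGains(Kp=g["Kp"], Ki=g["Ki"], Kd=g["Kd"])


def bands_from_config(cfg: dict) -> StabilityBands:
    return StabilityBands(rows=tuple(tuple(r) for r in cfg["bands"]))


def dppc_from_config(cfg: dict) -> DPPCConfig:
    d = cfg["dppc"]
    return DPPCConfig(
        margin=d["margin"],
        injection_phi=d["injection_phi"],
        replan_interval=d["replan_interval_s"],
        dt=d["dt_s"],
        coast_window=d["coast_window_s"],
        t1_max=d["t1_max_s"],
    )
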