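"""CSV / YAML I/O for drying curves and configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .curves import Conditions, DryingCurve

__all__ = ["read_curves", "write_curves", "load_config"]

_META_DEFAULTS = {
    "temp_C": 40.0,
    "pressure_kPa": 0.0,
    "thickness_m": 0.01,
    "initial_moisture_wb": 0.855,
    "equilibrium_moisture_wb": None,
}


def load_config(path: Union[str, Path, None]) -> Dict:
    """Load a YAML key-value config; returns {} for None."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _conditions_from(meta: Dict) -> Conditions:
    return Conditions(
        temperature_C=float(meta["temp_C"]),
        pressure_kPa=float(meta["pressure_kPa"]),
        layer_thickness_m=float(meta["thickness_m"]),
        initial_moisture_wb=float(meta["initial_moisture_wb"]),
        equilibrium_moisture_wb=(
            None
            if meta.get("equilibrium_moisture_wb") is None
            else float(meta["equilibrium_moisture_wb"])
        ),
    )


def read_curves(
    path: Union[str, Path], config: Union[Dict, str, Path, None] = None
) -> List[DryingCurve]:
    """Read drying curves from CSV.

    Expects a ``time_min`` column and at least one of ``weight_g`` /
    ``mr``.  Multiple curves share one file via a ``label`` column
    (long format).  Condition metadata comes from constant columns
    (``temp_C``, ``pressure_kPa``, ``thickness_m``, ...) or from a
    sidecar config (dict or YAML path); column values win over config.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValueError("missing required column 'time_min'")
    if "weight_g" not in df.columns and "mr" not in df.columns:
        raise ValueError("need a 'weight_g' or 'mr' column")

    groups = df.groupby("label", sort=False) if "label" in df.columns else [("", df)]
    curves = []
    for label, sub in groups:
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"curve {label!r}: times not strictly increasing")
        meta = dict(_META_DEFAULTS)
        meta.update({k: v for k, v in cfg.items() if k in _META_DEFAULTS})
        for col in _META_DEFAULTS:
            if col in sub.columns:
                vals = sub[col].dropna().unique()
                if len(vals) > 1:
                    raise ValueError(f"curve {label!r}: non-constant metadata {col}")
                if len(vals):
                    meta[col] = vals[0]
        curves.append(
            DryingCurve(
                times_min=times,
                conditions=_conditions_from(meta),
                weights_g=sub["weight_g"].to_numpy(dtype=float)
                if "weight_g" in sub.columns
                else None,
                moisture_ratio=sub["mr"].to_numpy(dtype=float)
                if "mr" in sub.columns
                else None,
                label=str(label),
            )
        )
    return curves


def write_curves(curves: List[DryingCurve], path: Union[str, Path]) -> None:
    """Write curves to the long-format CSV dialect read by read_curves."""
    frames = []
    for curve in curves:
        c = curve.conditions
        data = {
            "label": curve.label,
            "time_min": curve.times_min,
            "temp_C": c.temperature_C,
            "pressure_kPa": c.pressure_kPa,
            "thickness_m": c.layer_thickness_m,
            "initial_moisture_wb": c.initial_moisture_wb,
        }
        if c.equilibrium_moisture_wb is not None:
            data["equilibrium_moisture_wb"] = c.equilibrium_moisture_wb
        if curve.weights_g is not None:
            data["weight_g"] = curve.weights_g
        if curve.moisture_ratio is not None:
            data["mr"] = curve.moisture_ratio
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
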