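"""End-to-end analysis pipeline.

Ties the stages together per the study workflow: per-curve exponential
drying constant and model ranking → effective diffusivity → per-pressure
Arrhenius activation energy → transition-state thermodynamics →
economics.  Stage failures are isolated: one curve's (or one model's)
failure annotates its own record and the run continues.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .curves import DryingCurve, moisture_ratio_series
from .diffusion import arrhenius_fit, deff_from_curve
from .economics import EconomicScenario, evaluate_scenario
from .models import MODELS, FitFailureError, fit_drying_constant, fit_model, rank_models
from .thermo import enthalpy_ea_convention, eyring_fit

__all__ = ["AnalysisReport", "run_full_pipeline"]

logger = logging.getLogger("vacudry")


@dataclass
class AnalysisReport:
    """JSON-serializable report mirroring the study's result tables."""

    curves: List[Dict] = field(default_factory=list)
    arrhenius: List[Dict] = field(default_factory=list)
    thermodynamics: List[Dict] = field(default_factory=list)
    economics: List[Dict] = field(default_factory=list)
    provenance: Dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def _fit_record(fit) -> Dict:
    return {
        "model_id": fit.model_id,
        "params": fit.params,
        "std_errors": fit.std_errors,
        "p_values": fit.p_values,
        "significant": fit.significant,
        "rmse": fit.rmse,
        "r_squared": fit.r_squared,
        "adj_r_squared": fit.adj_r_squared,
        "n_obs": fit.n_obs,
        "n_params": fit.n_params,
    }


def _analyze_curve(curve: DryingCurve, models: Sequence[str]) -> Dict:
    rec: Dict = {
        "label": curve.label,
        "temperature_C": curve.conditions.temperature_C,
        "pressure_kPa": curve.conditions.pressure_kPa,
        "n_points": len(curve),
        "batch_time_min": float(curve.times_min[-1]),
    }
    if curve.moisture_ratio is None:
        curve = moisture_ratio_series(curve)
    exp_fit = fit_drying_constant(curve)
    rec["drying_constant"] = {
        "k_per_min": exp_fit.k,
        "A": exp_fit.A,
        "r_squared": exp_fit.r_squared,
    }
    diff = deff_from_curve(curve)
    rec["diffusivity"] = {
        "d_eff_m2_s": diff.d_eff_m2_s,
        "slope_per_min": diff.slope_per_min,
        "intercept": diff.intercept,
        "r_squared": diff.r_squared,
        "half_thickness_m": diff.half_thickness_m,
        "physical": diff.physical,
    }
    fits = []
    errors = {}
    for model_id in models:
        try:
            fits.append(fit_model(model_id, curve))
        except (FitFailureError, ValueError, ZeroDivisionError) as exc:
            errors[model_id] = str(exc)
    ranked = rank_models(fits) if fits else []
    rec["model_fits"] = [_fit_record(f) for f in ranked]
    rec["best_model"] = ranked[0].model_id if ranked else None
    if errors:
        rec["model_errors"] = errors
    return rec


def run_full_pipeline(
    curves: Sequence[DryingCurve],
    scenario: Optional[EconomicScenario] = None,
    models: Optional[Sequence[str]] = None,
    eyring_k_unit: str = "s^-1",
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Run kinetics, diffusivity, Arrhenius, thermodynamics and economics.

    Arrhenius/thermodynamic stages run per pressure group and need at
    least two temperatures in the group; otherwise that group is
    skipped with a warning.  When ``scenario`` is given, the economics
    stage is evaluated once per curve using the curve's final time as
    the batch drying time.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves supplied")
    if models is None:
        models = sorted(MODELS)

    report = AnalysisReport()
    report.provenance = {
        "package_version": _pkg_version,
        "seed": seed,
        "n_curves": len(curves),
        "models": list(models),
        "eyring_k_unit": eyring_k_unit,
    }

    for curve in curves:
        t0 = time.perf_counter()
        try:
            rec = _analyze_curve(curve, models)
        except Exception as exc:  # stage isolation: poison only this curve
            rec = {"label": curve.label, "error": str(exc)}
            logger.warning("curve %s failed: %s", curve.label, exc)
        logger.info("curve %s analyzed in %.2fs", curve.label, time.perf_counter() - t0)
        report.curves.append(rec)

    good = [r for r in report.curves if "error" not in r]
    by_pressure: Dict[float, List[Dict]] = {}
    for rec in good:
        by_pressure.setdefault(rec["pressure_kPa"], []).append(rec)

    for pressure, group in sorted(by_pressure.items()):
        temps = {r["temperature_C"] for r in group}
        if len(temps) < 2:
            logger.warning(
                "pressure %s kPa: <2 temperatures, Arrhenius/thermo skipped", pressure
            )
            continue
        pts = [
            (r["temperature_C"] + 273.15, r["diffusivity"]["d_eff_m2_s"]) for r in group
        ]
        arr = arrhenius_fit(pts)
        report.arrhenius.append(
            {
                "pressure_kPa": pressure,
                "activation_energy_kJ_mol": arr.activation_energy_kJ_mol,
                "d0_m2_s": arr.d0_m2_s,
                "r_squared": arr.r_squared,
                "temperatures_K": list(arr.temperatures_K),
            }
        )
        scale = 1.0 / 60.0 if eyring_k_unit == "s^-1" else 1.0
        k_pts = [
            (r["temperature_C"] + 273.15, r["drying_constant"]["k_per_min"] * scale)
            for r in group
        ]
        eyr = eyring_fit(k_pts, k_unit=eyring_k_unit)
        for T, _ in sorted(k_pts):
            dh = enthalpy_ea_convention(arr.activation_energy_J_mol, T)
            report.thermodynamics.append(
                {
                    "pressure_kPa": pressure,
                    "temperature_K": T,
                    "delta_h_kJ_mol": dh / 1e3,
                    "delta_s_kJ_molK": eyr.delta_s_J_molK / 1e3,
                    "delta_g_kJ_mol": (dh - T * eyr.delta_s_J_molK) / 1e3,
                    "delta_h_eyring_kJ_mol": eyr.delta_h_J_mol / 1e3,
                    "k_unit": eyr.k_unit,
                }
            )

    if scenario is not None:
        for rec in good:
            econ = evaluate_scenario(
                EconomicScenario(
                    **{
                        **{
                            f: getattr(scenario, f)
                            for f in scenario.__dataclass_fields__
                        },
                        "batch_time_min": rec["batch_time_min"],
                    }
                )
            )
            row = econ.as_dict()
            row["label"] = rec["label"]
            report.economics.append(row)
    return report
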