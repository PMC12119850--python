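"""Synthetic drying-curve generator.

Emulates a load-cell-instrumented batch vacuum dryer: 100 g herb
samples at 85.5% wet-basis initial moisture, weighed every 15 minutes,
drying toward an equilibrium moisture of ~13.4% wet basis, with the
moisture ratio following a Page-type decay whose rate constant depends
on drying temperature (40/50/60 °C) and gauge pressure (0/−5/−10 kPa).
Weight noise is additive Gaussian in the weight domain (balance
accuracy ±0.1 g by default), applied i.i.d. to every reading.

The generated moisture ratio is anchored at the equilibrium moisture:
M_t = M_e + MR·(M_0 − M_e) on a dry basis, then converted to weights by
mass balance, so the weight trace ends near the equilibrium weight
(≈16.7 g for the default 100 g sample) rather than bone dry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .curves import Conditions, DryingCurve, wb_to_db
from .models import predict_mr

__all__ = [
    "DEFAULT_RATE_CONSTANTS",
    "GeneratorSpec",
    "generate_curve",
    "generate_grid",
]

# Default true drying constants (min^-1) over the 3 temperature x 3
# pressure study grid; keys are (temperature_C, gauge_pressure_kPa).
DEFAULT_RATE_CONSTANTS: Dict[Tuple[float, float], float] = {
    (40.0, 0.0): 0.0069,
    (50.0, 0.0): 0.0116,
    (60.0, 0.0): 0.0164,
    (40.0, -5.0): 0.0124,
    (50.0, -5.0): 0.0143,
    (60.0, -5.0): 0.0195,
    (40.0, -10.0): 0.0171,
    (50.0, -10.0): 0.0240,
    (60.0, -10.0): 0.0398,
}


def _default_params() -> Dict[Tuple[float, float], Dict[str, float]]:
    return {
        cond: {"k": k, "n": 1.0} for cond, k in DEFAULT_RATE_CONSTANTS.items()
    }


@dataclass(frozen=True)
class GeneratorSpec:
    """Generator configuration; the seed fully determines the output."""

    model: str = "page"
    true_params: Dict[Tuple[float, float], Dict[str, float]] = field(
        default_factory=_default_params
    )
    sampling_interval_min: float = 15.0
    max_time_min: float = 510.0
    mr_stop: float = 0.01
    initial_mass_g: float = 100.0
    initial_moisture_wb: float = 0.855
    equilibrium_moisture_wb: float = 0.134
    layer_thickness_m: float = 0.01
    noise_sd_g: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be non-negative")
        if not (0 <= self.equilibrium_moisture_wb < self.initial_moisture_wb < 1):
            raise ValueError("need 0 <= equilibrium < initial moisture < 1")
        if self.sampling_interval_min <= 0 or self.max_time_min <= 0:
            raise ValueError("sampling interval and horizon must be positive")


def _time_grid(spec: GeneratorSpec, params: Dict[str, float]) -> np.ndarray:
    """Times every sampling interval until MR <= mr_stop or the horizon."""
    times = np.arange(
        0.0, spec.max_time_min + spec.sampling_interval_min / 2, spec.sampling_interval_min
    )
    mr = np.asarray(predict_mr(spec.model, params, times))
    below = np.nonzero(mr <= spec.mr_stop)[0]
    if below.size:
        times = times[: below[0] + 1]  # include the first point at/below the stop
    return times


def generate_curve(
    spec: GeneratorSpec,
    condition: Tuple[float, float],
    rng: Optional[np.random.Generator] = None,
) -> DryingCurve:
    """Generate one noisy weight curve for (temperature_C, pressure_kPa).

    MR comes from the closed-form kinetic model, is converted to a
    weight trace via the dry-matter mass balance, and i.i.d. Gaussian
    weight noise is added.  Reproducible under the spec seed.
    """
    cond = (float(condition[0]), float(condition[1]))
    try:
        params = spec.true_params[cond]
    except KeyError:
        raise KeyError(f"no true parameters for condition {cond}") from None
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    times = _time_grid(spec, params)
    mr = np.asarray(predict_mr(spec.model, params, times))

    dry = spec.initial_mass_g * (1.0 - spec.initial_moisture_wb)
    m0 = wb_to_db(spec.initial_moisture_wb)
    me = wb_to_db(spec.equilibrium_moisture_wb)
    moisture_db = me + mr * (m0 - me)
    weights = dry * (1.0 + moisture_db)
    if spec.noise_sd_g > 0:
        weights = weights + rng.normal(0.0, spec.noise_sd_g, size=weights.shape)
        weights = np.maximum(weights, dry * 1e-3)  # load cell cannot read <= 0

    conditions = Conditions(
        temperature_C=cond[0],
        pressure_kPa=cond[1],
        layer_thickness_m=spec.layer_thickness_m,
        initial_moisture_wb=spec.initial_moisture_wb,
        equilibrium_moisture_wb=spec.equilibrium_moisture_wb,
    )
    label = f"T{cond[0]:g}C_P{cond[1]:g}kPa"
    return DryingCurve(
        times_min=times, conditions=conditions, weights_g=weights, label=label
    )


def generate_grid(spec: GeneratorSpec) -> Tuple[List[DryingCurve], Dict]:
    """Generate one curve per configured condition plus a truth manifest.

    The manifest records the generating model and true parameters so
    downstream parameter-recovery scoring needs no side channel.
    """
    rng = np.random.default_rng(spec.seed)
    curves = []
    manifest: Dict = {
        "model": spec.model,
        "seed": spec.seed,
        "noise_sd_g": spec.noise_sd_g,
        "conditions": [],
    }
    for cond in sorted(spec.true_params):
        curve = generate_curve(spec, cond, rng=rng)
        curves.append(curve)
        manifest["conditions"].append(
            {
                "temperature_C": cond[0],
                "pressure_kPa": cond[1],
                "label": curve.label,
                "true_params": dict(spec.true_params[cond]),
            }
        )
    return curves, manifest
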