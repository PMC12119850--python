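"""Drying-curve data model and elementary kinetic transforms.

A drying experiment is a time series of sample weights (or moisture
ratios) recorded under fixed chamber conditions.  Everything downstream
— thin-layer model fits, diffusivity, thermodynamics — consumes the
:class:`DryingCurve` container defined here.

Moisture contents are carried dry-basis internally (water mass per unit
dry-matter mass); wet-basis fractions appear only at the I/O boundary.
Time is minutes everywhere in the data model; operations needing hours
or seconds convert internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Conditions",
    "DryingCurve",
    "RateSeries",
    "moisture_content_dry_basis",
    "convert_moisture_basis",
    "wb_to_db",
    "db_to_wb",
    "weight_loss_series",
    "drying_rate_series",
    "moisture_ratio_series",
]

ABSOLUTE_ZERO_C = -273.15


@dataclass(frozen=True)
class Conditions:
    """Chamber conditions for one drying run.

    Parameters
    ----------
    temperature_C : float
        Drying air temperature in °C.
    pressure_kPa : float
        Gauge pressure in kPa; 0 means atmospheric, negative values are
        vacuum (e.g. -10 kPa).
    layer_thickness_m : float
        Full product layer thickness in metres (0.01 m for a 1 cm bed).
    initial_moisture_wb : float
        Initial moisture content, wet-basis fraction in [0, 1).
    equilibrium_moisture_wb : float, optional
        Equilibrium moisture content, wet-basis fraction; must be below
        the initial moisture when present.
    """

    temperature_C: float
    pressure_kPa: float = 0.0
    layer_thickness_m: float = 0.01
    initial_moisture_wb: float = 0.855
    equilibrium_moisture_wb: Optional[float] = None

    def __post_init__(self) -> None:
        if self.temperature_C <= ABSOLUTE_ZERO_C:
            raise ValueError(f"temperature {self.temperature_C} °C below absolute zero")
        if self.layer_thickness_m <= 0:
            raise ValueError("layer_thickness_m must be positive")
        if not (0 <= self.initial_moisture_wb < 1):
            raise ValueError("initial_moisture_wb must lie in [0, 1)")
        if self.equilibrium_moisture_wb is not None:
            if not (0 <= self.equilibrium_moisture_wb < 1):
                raise ValueError("equilibrium_moisture_wb must lie in [0, 1)")
            if self.equilibrium_moisture_wb >= self.initial_moisture_wb:
                raise ValueError("equilibrium moisture must be below initial moisture")

    @property
    def temperature_K(self) -> float:
        """Absolute drying temperature in kelvin."""
        return self.temperature_C + 273.15

    @property
    def half_thickness_m(self) -> float:
        """Half layer thickness L used by the slab diffusion solution."""
        return self.layer_thickness_m / 2.0


@dataclass(frozen=True)
class DryingCurve:
    """One condition's drying time series.

    At least one of ``weights_g`` and ``moisture_ratio`` must be given;
    times are strictly increasing minutes starting at 0.
    """

    times_min: np.ndarray
    conditions: Conditions
    weights_g: Optional[np.ndarray] = None
    moisture_ratio: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        object.__setattr__(self, "times_min", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("times_min must be a 1-D sequence of at least 2 points")
        if t[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.weights_g is None and self.moisture_ratio is None:
            raise ValueError("need weights_g or moisture_ratio")
        for name in ("weights_g", "moisture_ratio"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                object.__setattr__(self, name, arr)
                if arr.shape != t.shape:
                    raise ValueError(f"{name} length must match times_min")
        if self.weights_g is not None and np.any(self.weights_g <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return int(self.times_min.size)

    @property
    def dry_matter_g(self) -> Optional[float]:
        """Dry-matter mass inferred from the first weight and the
        initial wet-basis moisture; None when weights are absent."""
        if self.weights_g is None:
            return None
        return float(self.weights_g[0] * (1.0 - self.conditions.initial_moisture_wb))

    def with_moisture_ratio(self, mr: np.ndarray) -> "DryingCurve":
        return replace(self, moisture_ratio=np.asarray(mr, dtype=float))


@dataclass(frozen=True)
class RateSeries:
    """Per-interval drying rates at interval midpoints.

    ``rates_g_per_h`` is raw mass loss per hour; ``specific_rates`` is
    g water / g dry matter / h when dry matter is known.
    """

    midpoints_min: np.ndarray
    rates_g_per_h: np.ndarray
    specific_rates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("midpoints_min", "rates_g_per_h", "specific_rates"):
            arr = getattr(self, name)
            if arr is not None:
                object.__setattr__(self, name, np.asarray(arr, dtype=float))
        if self.midpoints_min.shape != self.rates_g_per_h.shape:
            raise ValueError("midpoints and rates must have equal length")
        if not np.all(np.isfinite(self.rates_g_per_h)):
            raise ValueError("rates must be finite")


def moisture_content_dry_basis(wet_weight_g: float, dry_weight_g: float) -> float:
    """Dry-basis moisture content in percent, 100·(W_w − W_d)/W_d.

    This is the oven-method definition: water mass relative to the
    bone-dry matter mass.
    """
    if dry_weight_g <= 0:
        raise ValueError("dry weight must be positive")
    if wet_weight_g < dry_weight_g:
        raise ValueError("wet weight cannot be below dry weight")
    return 100.0 * (wet_weight_g - dry_weight_g) / dry_weight_g


def wb_to_db(wb: float) -> float:
    """Wet-basis fraction → dry-basis ratio: db = wb/(1−wb)."""
    wb = float(wb)
    if not (0 <= wb < 1):
        raise ValueError("wet-basis moisture must lie in [0, 1)")
    return wb / (1.0 - wb)


def db_to_wb(db: float) -> float:
    """Dry-basis ratio → wet-basis fraction: wb = db/(1+db)."""
    db = float(db)
    if db < 0:
        raise ValueError("dry-basis moisture must be non-negative")
    return db / (1.0 + db)


def convert_moisture_basis(value: float, direction: str) -> float:
    """Convert a moisture fraction between wet and dry basis.

    ``direction`` is ``"wb->db"`` or ``"db->wb"``.  The two conversions
    are exact inverses of each other.
    """
    if direction == "wb->db":
        return wb_to_db(value)
    if direction == "db->wb":
        return db_to_wb(value)
    raise ValueError(f"unknown direction {direction!r}; use 'wb->db' or 'db->wb'")


def weight_loss_series(curve: DryingCurve) -> np.ndarray:
    """Per-interval weight losses W_t − W_{t+1} in grams.

    The cumulative sum telescopes to first-minus-last weight exactly.
    """
    if curve.weights_g is None:
        raise ValueError("curve has no weights; weight loss undefined")
    return -np.diff(curve.weights_g)


def drying_rate_series(
    curve: DryingCurve, dry_matter_g: Optional[float] = None
) -> RateSeries:
    """Drying rate per interval: weight loss divided by Δt in hours.

    When ``dry_matter_g`` is given (or derivable from the curve) the
    specific rate in g water / g dry matter / h is also filled.
    Negative instantaneous rates from weighing noise are retained.
    """
    losses = weight_loss_series(curve)
    dt_min = np.diff(curve.times_min)
    if np.any(dt_min <= 0):
        raise ValueError("duplicate or non-increasing time stamps")
    rates = losses / (dt_min / 60.0)
    mid = curve.times_min[:-1] + dt_min / 2.0
    if dry_matter_g is None:
        dry_matter_g = curve.dry_matter_g
    specific = rates / dry_matter_g if dry_matter_g else None
    return RateSeries(midpoints_min=mid, rates_g_per_h=rates, specific_rates=specific)


def _dry_basis_trace(curve: DryingCurve) -> np.ndarray:
    dm = curve.dry_matter_g
    if dm is None or dm <= 0:
        raise ValueError("moisture contents not derivable: weights and initial moisture required")
    return (curve.weights_g - dm) / dm


def moisture_ratio_series(curve: DryingCurve, use_equilibrium: bool = False) -> DryingCurve:
    """Fill the moisture-ratio trace of a weight-bearing curve.

    By default MR_t = M_t/M_0 (equilibrium moisture neglected, the
    customary simplification when M_e ≪ M_0).  With
    ``use_equilibrium=True`` and an equilibrium moisture on the
    conditions, MR_t = (M_t − M_e)/(M_0 − M_e).  MR_0 = 1 in both cases.
    """
    if curve.moisture_ratio is not None and curve.weights_g is None:
        return curve
    m = _dry_basis_trace(curve)
    m0 = m[0]
    me = None
    if use_equilibrium:
        e_wb = curve.conditions.equilibrium_moisture_wb
        me = wb_to_db(e_wb) if e_wb is not None else None
    if me is not None:
        if abs(m0 - me) < 1e-15:
            raise ZeroDivisionError("degenerate normalization: M_0 equals M_e")
        mr = (m - me) / (m0 - me)
    else:
        if m0 <= 0:
            raise ZeroDivisionError("degenerate normalization: M_0 is zero")
        mr = m / m0
    return curve.with_moisture_ratio(mr)
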