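"""Fick slab solution, effective moisture diffusivity and Arrhenius fit.

For an infinite slab of half-thickness L with uniform initial moisture
and a surface held at equilibrium, the moisture ratio is the series

    MR(t) = (8/π²) Σ_{n odd} (1/n²) exp(−n² π² D_eff t / 4L²)

whose first term dominates at long times, giving the log-linear form
ln MR = ln(8/π²) − π² D_eff t / 4L².  D_eff follows from the slope of
ln MR against time; its temperature dependence follows Arrhenius,
D_eff = D₀ exp(−E_a/RT), with E_a from the slope of ln D_eff vs 1/T.

L is the HALF layer thickness (0.005 m for a 1 cm bed): this is the
convention under which the drying-constant grid reproduces the study's
printed diffusivities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .curves import DryingCurve

__all__ = [
    "GAS_CONSTANT",
    "DiffusivityResult",
    "ArrheniusResult",
    "fick_mr_series",
    "deff_from_curve",
    "deff_from_k",
    "arrhenius_fit",
]

GAS_CONSTANT = 8.314  # J/(mol·K)

_PI2 = np.pi**2


@dataclass(frozen=True)
class DiffusivityResult:
    """Effective moisture diffusivity with its regression provenance."""

    d_eff_m2_s: float
    slope_per_min: float
    intercept: float
    r_squared: float
    half_thickness_m: float
    physical: bool = True  # False when the ln MR slope is non-negative


@dataclass(frozen=True)
class ArrheniusResult:
    """Arrhenius parameters of D_eff(T)."""

    activation_energy_J_mol: float
    d0_m2_s: float
    r_squared: float
    temperatures_K: Tuple[float, ...]

    @property
    def activation_energy_kJ_mol(self) -> float:
        return self.activation_energy_J_mol / 1e3


def fick_mr_series(d_eff: float, half_thickness: float, t_s, n_terms: int = 50):
    """Truncated slab-series MR at time t (seconds).

    Sums the first ``n_terms`` odd-index terms; with ``n_terms=1`` this
    is (8/π²)·exp(−π² D_eff t / 4L²).  The sum at t = 0 approaches 1 as
    the truncation grows (Σ 1/n² over odd n = π²/8).
    """
    if d_eff <= 0 or half_thickness <= 0:
        raise ValueError("d_eff and half_thickness must be positive")
    if n_terms < 1:
        raise ValueError("n_terms must be at least 1")
    t = np.asarray(t_s, dtype=float)
    n = np.arange(1, 2 * n_terms, 2, dtype=float)  # odd indices
    fo = _PI2 * d_eff * t[..., None] / (4.0 * half_thickness**2)
    series = np.sum(np.exp(-np.square(n) * fo) / np.square(n), axis=-1)
    out = (8.0 / _PI2) * series
    return out if out.ndim else float(out)


def deff_from_curve(curve: DryingCurve, half_thickness: float = None) -> DiffusivityResult:
    """Effective diffusivity from the ln MR vs time regression.

    OLS with an intercept (not forced through ln(8/π²)); points with
    MR ≤ 0 are excluded.  The minute-domain slope is converted to s⁻¹
    and D_eff = −slope · 4L²/π².  A non-negative slope is flagged
    non-physical and returned with a warning rather than raised.
    """
    if curve.moisture_ratio is None:
        raise ValueError("curve has no moisture-ratio trace; derive it first")
    if half_thickness is None:
        half_thickness = curve.conditions.half_thickness_m
    if half_thickness <= 0:
        raise ValueError("half_thickness must be positive")
    mr = curve.moisture_ratio
    mask = mr > 0
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points with MR > 0")
    res = stats.linregress(curve.times_min[mask], np.log(mr[mask]))
    slope_s = res.slope / 60.0
    d_eff = -slope_s * 4.0 * half_thickness**2 / _PI2
    physical = res.slope < 0
    if not physical:
        warnings.warn("non-negative ln MR slope: D_eff flagged non-physical")
    return DiffusivityResult(
        d_eff_m2_s=float(d_eff),
        slope_per_min=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        half_thickness_m=float(half_thickness),
        physical=bool(physical),
    )


def deff_from_k(k_per_min: float, half_thickness: float) -> float:
    """Diffusivity implied by an exponential drying constant.

    Identifies the first-term slab slope with the drying constant:
    D_eff = (k/60) · 4L² / π², k in min⁻¹, L the half thickness in m.
    """
    if k_per_min <= 0 or half_thickness <= 0:
        raise ValueError("k and half_thickness must be positive")
    return (k_per_min / 60.0) * 4.0 * half_thickness**2 / _PI2


def arrhenius_fit(points: Sequence[Tuple[float, float]]) -> ArrheniusResult:
    """Arrhenius regression of ln D_eff on 1/T.

    ``points`` are (temperature K, D_eff m²/s) pairs at two or more
    distinct temperatures.  E_a = −slope·R, D₀ = exp(intercept).
    """
    pts = [(float(T), float(d)) for T, d in points]
    temps = [T for T, _ in pts]
    if len(set(temps)) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    if any(d <= 0 for _, d in pts):
        raise ValueError("all D_eff values must be positive")
    x = 1.0 / np.array(temps)
    y = np.log([d for _, d in pts])
    res = stats.linregress(x, y)
    return ArrheniusResult(
        activation_energy_J_mol=float(-res.slope * GAS_CONSTANT),
        d0_m2_s=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        temperatures_K=tuple(temps),
    )
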