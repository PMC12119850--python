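"""Transition-state (Eyring) thermodynamics of the drying rate process.

The Eyring relation linearizes as

    ln(k/T) = ln(k_B/h) + ΔS‡/R − (ΔH‡/R)(1/T)

so a regression of ln(k/T) on 1/T yields the activation enthalpy ΔH‡
from the slope and the activation entropy ΔS‡ from the intercept.  ΔS‡
depends on the unit of the rate constant (ln k shifts by ln 60 between
min⁻¹ and s⁻¹), so every result carries a mandatory unit tag.

A second, per-temperature enthalpy convention ΔH‡(T) = E_a − R·T is
provided: it ties the enthalpy directly to the Arrhenius activation
energy and gives the small (≈0.08 kJ/mol per 10 K) decrease of ΔH‡
with temperature seen in falling-rate drying studies.

Gibbs free energy of activation: ΔG‡ = ΔH‡ − TΔS‡.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .diffusion import GAS_CONSTANT

__all__ = [
    "BOLTZMANN",
    "PLANCK",
    "EyringFit",
    "eyring_fit",
    "enthalpy_ea_convention",
    "gibbs_free_energy",
]

BOLTZMANN = 1.38065e-23  # J/K
PLANCK = 6.62608e-34  # J·s


@dataclass(frozen=True)
class EyringFit:
    """Eyring regression result; entropies are tied to the k unit."""

    delta_h_J_mol: float
    delta_s_J_molK: float
    r_squared: float
    k_unit: str
    temperatures_K: Tuple[float, ...]

    def gibbs(self, T: float) -> float:
        """ΔG‡ = ΔH‡ − TΔS‡ at temperature T (K), in J/mol."""
        return gibbs_free_energy(self.delta_h_J_mol, self.delta_s_J_molK, T)


def eyring_fit(points: Sequence[Tuple[float, float]], k_unit: str = "s^-1") -> EyringFit:
    """Fit ln(k/T) against 1/T for (T in K, rate constant k) pairs.

    slope = −ΔH‡/R and intercept = ln(k_B/h) + ΔS‡/R.  ``k_unit`` tags
    the unit the rate constants are expressed in ('s^-1' or 'min^-1');
    it does not convert — pass the constants already in that unit.
    """
    pts = [(float(T), float(k)) for T, k in points]
    if len({T for T, _ in pts}) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    if any(k <= 0 or T <= 0 for T, k in pts):
        raise ValueError("temperatures and rate constants must be positive")
    x = 1.0 / np.array([T for T, _ in pts])
    y = np.log(np.array([k for _, k in pts]) / np.array([T for T, _ in pts]))
    res = stats.linregress(x, y)
    delta_h = -float(res.slope) * GAS_CONSTANT
    delta_s = GAS_CONSTANT * (float(res.intercept) - math.log(BOLTZMANN / PLANCK))
    return EyringFit(
        delta_h_J_mol=delta_h,
        delta_s_J_molK=delta_s,
        r_squared=float(res.rvalue**2),
        k_unit=k_unit,
        temperatures_K=tuple(T for T, _ in pts),
    )


def enthalpy_ea_convention(activation_energy_J_mol: float, T: float) -> float:
    """Per-temperature activation enthalpy ΔH‡(T) = E_a − R·T (J/mol)."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    return activation_energy_J_mol - GAS_CONSTANT * T


def gibbs_free_energy(delta_h_J_mol: float, delta_s_J_molK: float, T: float) -> float:
    """Gibbs free energy of activation ΔG‡ = ΔH‡ − TΔS‡ (J/mol)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return delta_h_J_mol - T * delta_s_J_molK
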