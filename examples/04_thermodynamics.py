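"""Transition-state thermodynamics of the drying rate process.

Eyring regression of ln(k/T) on 1/T gives the activation entropy; the
per-temperature convention dH = E_a - R*T gives the activation enthalpy;
dG = dH - T*dS closes the table.  Positive dH and dG with negative dS
mark drying as endothermic, non-spontaneous and order-increasing.
"""

from vacudry import (
    DEFAULT_RATE_CONSTANTS,
    arrhenius_fit,
    deff_from_k,
    enthalpy_ea_convention,
    eyring_fit,
    gibbs_free_energy,
)

TEMPS_K = {40.0: 313.15, 50.0: 323.15, 60.0: 333.15}
L = 0.005

print(f"{'P (kPa)':>8}{'T (K)':>9}{'dH (kJ/mol)':>13}{'dS (kJ/mol K)':>15}{'dG (kJ/mol)':>13}")
for pressure in (0.0, -5.0, -10.0):
    d_pts = [(TEMPS_K[T], deff_from_k(DEFAULT_RATE_CONSTANTS[(T, pressure)], L))
             for T in TEMPS_K]
    ea = arrhenius_fit(d_pts).activation_energy_J_mol
    k_pts = [(TEMPS_K[T], DEFAULT_RATE_CONSTANTS[(T, pressure)] / 60.0) for T in TEMPS_K]
    eyr = eyring_fit(k_pts, k_unit="s^-1")
    for T in sorted(TEMPS_K.values()):
        dh = enthalpy_ea_convention(ea, T)
        dg = gibbs_free_energy(dh, eyr.delta_s_J_molK, T)
        print(f"{pressure:>8.0f}{T:>9.2f}{dh/1e3:>13.2f}{eyr.delta_s_J_molK/1e3:>15.4f}{dg/1e3:>13.2f}")
print("\n(dS is tagged to s^-1 rate constants; it shifts by R ln 60 for min^-1)")
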