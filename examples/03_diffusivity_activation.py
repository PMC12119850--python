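"""Effective moisture diffusivity per condition and Arrhenius E_a.

The ln(moisture ratio) vs time slope of each curve gives D_eff through
the slab solution (half thickness L = 5 mm for a 1 cm layer); regressing
ln D_eff on 1/T per pressure gives the activation energy.
"""

from vacudry import (
    GeneratorSpec,
    arrhenius_fit,
    deff_from_curve,
    generate_grid,
    moisture_ratio_series,
)

curves, _ = generate_grid(GeneratorSpec(noise_sd_g=0.0))
by_pressure = {}
print(f"{'condition':<16}{'D_eff (m2/s)':>14}{'R2':>9}")
for c in curves:
    mr = moisture_ratio_series(c, use_equilibrium=True)
    res = deff_from_curve(mr)
    print(f"{c.label:<16}{res.d_eff_m2_s:>14.3e}{res.r_squared:>9.4f}")
    by_pressure.setdefault(c.conditions.pressure_kPa, []).append(
        (c.conditions.temperature_K, res.d_eff_m2_s)
    )

print("\nArrhenius activation energy (kJ/mol) per operating pressure:")
for pressure, points in sorted(by_pressure.items()):
    fit = arrhenius_fit(points)
    print(f"  {pressure:>6.0f} kPa: E_a = {fit.activation_energy_kJ_mol:.1f}, "
          f"D0 = {fit.d0_m2_s:.2e} m2/s (energy barrier for moisture diffusion)")
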