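"""End-to-end pipeline: simulate the grid, analyze every stage, report.

One call produces the per-condition kinetics and diffusivity, the
per-pressure activation energies and thermodynamics, and the economics
of every condition, as one JSON-serializable report.
"""

from vacudry import (
    EconomicScenario,
    GeneratorSpec,
    generate_grid,
    moisture_ratio_series,
    run_full_pipeline,
)

curves, truth = generate_grid(GeneratorSpec(seed=1, noise_sd_g=0.1))
curves = [moisture_ratio_series(c, use_equilibrium=True) for c in curves]
report = run_full_pipeline(curves, scenario=EconomicScenario(batch_time_min=90.0), seed=1)

print("per-condition drying constants (fitted vs true):")
true_k = {c["label"]: c["true_params"]["k"] for c in truth["conditions"]}
for rec in report.curves:
    k = rec["drying_constant"]["k_per_min"]
    print(f"  {rec['label']:<16} k = {k:.4f} min^-1 (true {true_k[rec['label']]:.4f}), "
          f"best model: {rec['best_model']}")

print("\nactivation energies (kJ/mol):")
for row in report.arrhenius:
    print(f"  {row['pressure_kPa']:>6.0f} kPa: {row['activation_energy_kJ_mol']:.1f}")

fastest = min(report.economics, key=lambda r: r["payback_years"])
print(f"\nfastest payback: {fastest['payback_months']:.1f} months "
      f"at {fastest['label']}")
print(f"report sections: {len(report.curves)} curves, "
      f"{len(report.arrhenius)} Arrhenius fits, "
      f"{len(report.thermodynamics)} thermo rows, "
      f"{len(report.economics)} economic scenarios")
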