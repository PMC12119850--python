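"""Fit the nine-model thin-layer bank to one curve and rank the fits.

Shows the Table-of-fits workflow: each model's parameters, standard
errors, significance at p <= 0.05, and RMSE / adjusted R-squared based
model selection (smaller RMSE is better).
"""

from vacudry import (
    MODELS,
    GeneratorSpec,
    fit_model,
    generate_curve,
    moisture_ratio_series,
    page_weibull_equivalents,
    rank_models,
)

spec = GeneratorSpec(seed=11)
curve = moisture_ratio_series(generate_curve(spec, (50.0, -5.0)), use_equilibrium=True)

fits = rank_models([fit_model(model_id, curve) for model_id in sorted(MODELS)])
print(f"{'model':<20}{'RMSE':>10}{'adj R2':>10}  parameters")
for f in fits:
    pars = ", ".join(f"{k}={v:.4g}" for k, v in f.params.items())
    print(f"{f.model_id:<20}{f.rmse:>10.5f}{f.adj_r_squared:>10.5f}  {pars}")

best = fits[0]
print(f"\nbest model: {best.model_id} (lowest RMSE)")
if best.model_id == "page":
    eq = page_weibull_equivalents(best.params["k"], best.params["n"])
    print("equivalent Weibull scale alpha = "
          f"{eq['alpha']:.2f} min (characteristic drying time), "
          f"delta = {eq['delta']:.2f} min (base-10 form)")
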