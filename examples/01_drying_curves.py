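"""Generate one drying curve and walk through the elementary transforms.

A 100 g herb sample at 85.5% wet-basis moisture dries at 60 degC under
-10 kPa gauge vacuum; the load cell logs its weight every 15 minutes.
"""

import numpy as np

from vacudry import (
    GeneratorSpec,
    drying_rate_series,
    generate_curve,
    moisture_ratio_series,
    weight_loss_series,
)

spec = GeneratorSpec(seed=7)
curve = generate_curve(spec, (60.0, -10.0))
print(f"condition {curve.label}: {len(curve)} samples, "
      f"last at {curve.times_min[-1]:.0f} min")
print(f"weights (g): {np.round(curve.weights_g[:5], 2)} ...")

losses = weight_loss_series(curve)
print(f"total weight loss: {losses.sum():.2f} g "
      "(water removed down to near the equilibrium moisture)")

rates = drying_rate_series(curve)
print(f"peak drying rate: {rates.rates_g_per_h.max():.1f} g/h, "
      f"specific {rates.specific_rates.max():.2f} g water/g dry matter/h")

mr = moisture_ratio_series(curve, use_equilibrium=True).moisture_ratio
print(f"moisture ratio trace: 1.0 -> {mr[-1]:.4f} "
      "(fraction of removable moisture still present)")
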