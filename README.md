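# vacudry

Thin-layer drying kinetics, Fickian moisture diffusivity, transition-
state thermodynamics and batch-dryer techno-economics, in one tested
Python toolkit — built around the workflow of vacuum-drying studies of
leafy herbs (sage-type material: 100 g samples, ~85% initial moisture,
1 cm layers, load-cell weighing every 15 min over a 40–60 °C ×
0/−5/−10 kPa grid).

For process engineers and drying researchers who have weight-vs-time
curves and want the full analysis chain:

1. **Kinetics** — moisture ratio MR(t), drying rates, and the drying
   constant k from ln MR = ln A − kt.
2. **Model selection** — nine thin-layer models (Page `exp(−ktⁿ)`,
   Weibull, Midilli, logarithmic, Aghbashlo, Wang–Singh …) fitted by
   nonlinear least squares with SEs, p-values, RMSE = √(SSE/(n−p)),
   R² and adjusted R²; exact Page↔Weibull parameter algebra.
3. **Transport** — effective moisture diffusivity from the slab
   solution MR = (8/π²)Σ(1/n²)exp(−n²π²D_eff t/4L²) via the ln MR
   slope, and Arrhenius activation energy E_a from ln D_eff vs 1/T.
4. **Thermodynamics** — Eyring regression of ln(k/T) on 1/T for ΔS‡,
   the per-temperature enthalpy ΔH‡ = E_a − RT, and ΔG‡ = ΔH‡ − TΔS‡.
5. **Economics** — capital recovery factor, annualized costs, per-kg
   savings, and the inflation-adjusted payback
   Ŧ = ln[1 − (C_cc/S_1)(d−i)] / ln((1+i)/(1+d)).

A synthetic load-cell generator reproduces the study conditions so the
entire chain is verifiable end-to-end without any raw data download.
See `docs/methods.md` for models, conventions and limitations.

## Worked example

Diffusivity and activation energy from a noiseless simulated grid
(`examples/03_diffusivity_activation.py`):

```text
condition         D_eff (m2/s)       R2
T40C_P0kPa           1.165e-09   1.0000
T50C_P0kPa           1.959e-09   1.0000
T60C_P0kPa           2.769e-09   1.0000
T60C_P-10kPa         6.721e-09   1.0000
...

Arrhenius activation energy (kJ/mol) per operating pressure:
     -10 kPa: E_a = 36.6, D0 = 3.50e-03 m2/s
      -5 kPa: E_a = 19.6, D0 = 3.71e-06 m2/s
       0 kPa: E_a = 37.6, D0 = 2.24e-03 m2/s
```

Each D_eff is the ln MR slope of one curve mapped through the slab
geometry (half thickness L = 5 mm); raising temperature and deepening
vacuum both speed moisture transport, and E_a is the temperature
sensitivity of that transport at each pressure. The economics end of
the chain (`examples/05_economics.py`):

```text
 batch time   kg/year  S1 (USD)         payback
     510 min     823.5    617.65     0.500 yr ( 6.0 mo)
      90 min    4666.7   3500.00     0.088 yr ( 1.1 mo)

annualized investment cost: 19.16 USD/yr (capital 20.16 + maintenance 0.60 - salvage 1.61)
```

A 300 USD dryer running 2 kg batches pays for itself in about a month
at the fastest drying condition — shorter batches mean more batches per
day and proportionally larger first-year savings S1.

The other scripts in `examples/` walk through curve transforms, the
nine-model fit table, the thermodynamic table and the one-call
end-to-end report. A thin CLI mirrors the library
(`vacudry simulate|fit|diffusivity|arrhenius|thermo|econ|report`).

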