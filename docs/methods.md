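# Methods

`vacudry` models the batch drying of a thin layer of leafy herb in a
temperature- and pressure-controlled dryer, from the raw load-cell
weight log through kinetics, transport, thermodynamics and economics.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic data generator does and does not
emulate.

## Data model and kinetic transforms

A drying run is a strictly increasing time grid (minutes, starting at
0) with sample weights (g) and/or a moisture-ratio trace, plus chamber
conditions: drying temperature (°C), gauge pressure (kPa, 0 =
atmospheric), layer thickness (m), and initial / equilibrium wet-basis
moisture fractions. Moisture contents are carried dry basis internally
(M = water mass / dry-matter mass); wet basis appears only at I/O,
because the oven-method moisture definition 100·(W_w − W_d)/W_d is dry
basis. Dry matter is inferred from the first weight and the initial
wet-basis moisture.

The moisture ratio defaults to MR = M_t/M_0, neglecting the equilibrium
moisture — the customary simplification when M_e ≪ M_0; the full
normalization MR = (M_t − M_e)/(M_0 − M_e) is available with
`use_equilibrium=True` and is what the synthetic generator's truth is
anchored to, so round-trip tests use it. Negative instantaneous weight
losses from balance noise are retained in rate series (raw-data
fidelity); only log-domain regressions exclude MR ≤ 0 points.

Drying rate is per-interval mass loss over Δt in hours (g/h), and per
gram of dry matter when known. Because rates are interval-exact, their
time integral reproduces the total weight loss to rounding error — a
conservation property the tests assert.

## Thin-layer model bank

Nine closed-form MR(t) models: Page exp(−ktⁿ); Weibull exp(−(t/α)^β)
and its base-10 variant 10^(−(t/δ)ⁿ); Aghbashlo exp(−k₁t/(1+k₂t));
logarithmic a·exp(−kt)+c; Midilli a·exp(−ktⁿ)+bt and its two reduced
forms. Page and the two Weibull forms are reparameterizations of one
family: β = n, α = k^(−1/n), δ = α(ln 10)^(1/n), implemented as exact
algebra (`page_weibull_equivalents`) and verified point-identical.

Fitting is unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective with bounds).
Initialization: rate-like parameters (k, k₁) are seeded from the
log-linear drying constant, shape parameters at 1, offsets at 0, α at
1/k; up to 5 deterministically jittered restarts run before a fit is
declared failed. Bounds keep MR physically decaying without excluding
plausible estimates: k, k₁, α, δ > 0; n, β ∈ (0.05, 5); a ∈ (0, 2); b,
c and k₂ unbounded (k₂ may legitimately be negative). The Aghbashlo
exponent is clamped numerically so optimizer excursions through the
k₂t = −1 pole cannot overflow.

All goodness-of-fit statistics use n − p degrees of freedom: RMSE =
√(SSE/(n−p)), adjusted R² with (n−1)/(n−p), parameter standard errors
from the Jacobian-based covariance scaled by SSE/(n−p), and two-sided
t-test p-values on n − p dof (significance at p ≤ 0.05). Model ranking
is ascending RMSE, ties broken by descending adjusted R², then by fewer
parameters. A twice-refined brute-force grid search over the parameter
box serves as an independent optimum check in the tests (SSE agreement
to 0.1% on short curves).

The drying constant k (min⁻¹) is the slope of the ordinary
least-squares regression of ln MR on time (MR = A·exp(−kt)); points
with MR ≤ 0 are excluded, at least 3 usable points are required.

## Diffusivity and activation energy

For an infinite slab of half-thickness L, uniform initial moisture and
surface at equilibrium, Fick's second law gives

MR(t) = (8/π²) Σ_{n=1,3,5,…} (1/n²) exp(−n²π²D_eff t / 4L²).

The series is summed over odd indices with n² in the exponent (the
standard slab solution; the t = 0 sum then converges to 1). Its first
term gives the log-linear form ln MR = ln(8/π²) − π²D_eff t/4L², so the
ln MR slope (converted min⁻¹ → s⁻¹) yields D_eff = −slope·4L²/π²;
identifying the slope with the drying constant gives the shortcut
D_eff = (k/60)·4L²/π². **L is the half layer thickness** (0.005 m for
a 1 cm bed): this is the convention under which the drying-constant
grid reproduces the reference diffusivities (e.g. 0.0398 min⁻¹ →
6.72×10⁻⁹ m²/s), and it is configurable. The ln MR regression keeps a
free intercept (expected near ln(8/π²) ≈ −0.21) rather than forcing it;
a non-negative slope is flagged non-physical rather than raised, so
noisy plateau curves do not abort a batch run.

Activation energy comes from OLS of ln D_eff on 1/T (K = °C + 273.15):
E_a = −slope·R with R = 8.314 J/mol·K, D₀ = exp(intercept). E_a is
invariant to rescaling all D_eff by a constant, which the tests assert.

## Transition-state thermodynamics

The Eyring relation is used in its linearized form: regression of
ln(k/T) on 1/T gives ΔH‡ = −slope·R and ΔS‡ = R·(intercept −
ln(k_B/h)), with k_B = 1.38065×10⁻²³ J/K and h = 6.62608×10⁻³⁴ J·s.
ΔS‡ depends on the rate-constant unit — it shifts by exactly R·ln 60
between min⁻¹ and s⁻¹ — so every Eyring result carries a mandatory
unit tag; the default is s⁻¹.

The enthalpy is reported two ways. The regression slope gives one
temperature-independent ΔH‡; the per-temperature convention ΔH‡(T) =
E_a − R·T gives the small (R·10 ≈ 0.08 kJ/mol per 10 K) decrease with
temperature characteristic of falling-rate drying studies, and is the
one used in the summary tables. ΔG‡ = ΔH‡ − TΔS‡ exactly. On the
default study grid all three signs come out ΔH‡ > 0, ΔS‡ < 0, ΔG‡ > 0:
drying is endothermic, order-increasing at the activated state, and
non-spontaneous.

Known limitation: entropy magnitudes from the linearized Eyring
regression on drying constants are sensitive to the rate-constant unit
and to the absolute scale of k, and published drying studies are often
ambiguous about both; this package computes the regression faithfully
and makes the unit explicit rather than matching any particular
published ΔS‡ magnitude.

## Economics

Capital recovery factor F_c = d(1+d)^τ/((1+d)^τ−1) (limit 1/τ as d→0)
annualizes the capital cost; maintenance and salvage are fractions of
the annual capital cost (defaults 3% and 8%); C_a = C_ac + C_m − V_a.
Annual throughput is batches/day × batch mass × operating days, with
600 effective drying minutes per day by default — fractional batches
allowed — which is the convention that makes throughput scale exactly
inversely with batch time. Unit costs chain as C_s = C_a/M_y, C_ds =
C_dp + C_s, S_kg = SP − C_ds; the dried-product input cost C_ds can be
fixed directly (default 4.25 USD/kg, giving a flat 0.75 USD/kg margin
at a 5 USD/kg selling price) or derived from the fresh-herb cost and
the fresh-to-dried mass ratio when that is known. Savings cascade to
batch, day and year; payback is the closed form Ŧ = ln[1 −
(C_cc/S_1)(d−i)]/ln((1+i)/(1+d)), with the simple ratio C_cc/S_1 used
when d = i (the closed form's first-order limit as i→d is
(C_cc/S_1)(1+d), a ~3% difference at these rates). Monetary values are
kept at full precision and rounded to cents only at report time.

## Synthetic data generator

The generator emulates the study conditions: 100 g samples at 85.5%
wet-basis initial moisture (14.5 g dry matter), 1 cm layer, 15-minute
load-cell sampling, equilibrium moisture 13.4% wet basis, a 3×3 grid of
drying temperature (40/50/60 °C) × gauge pressure (0/−5/−10 kPa) with
Page-kinetics truth whose default rate constants span 0.0069–0.0398
min⁻¹ across the grid (n = 1 by default, so the drying-constant
regression is exactly consistent with the truth). Sampling stops at
MR ≤ 0.01 or 510 min, bracketing the 90–510 min range the fast and slow
corners of the grid imply.

Noise is additive i.i.d. Gaussian in the **weight domain** (load-cell
realism; default σ = 0.1 g, a typical balance accuracy), not in MR.
Because MR is computed from the noisy initial weight, the normalization
itself carries noise — a realism the recovery tests inherit. The truth
is equilibrium-anchored (M_t = M_e + MR·(M_0 − M_e)), so the weight
trace ends near the equilibrium weight (≈16.7 g; total loss ≈83.3 g)
rather than bone dry.

What the generator does not emulate: chamber humidity/temperature
sensor streams, warm-up transients, autocorrelated load-cell drift,
sample shrinkage or case hardening, or any dependence of the
equilibrium moisture on temperature and pressure. Passing tests
therefore demonstrate correctness of the estimators under the stated
kinetic + noise model, not robustness to those real-data effects.

## Pipeline and problem sizes

`run_full_pipeline` runs per-curve kinetics (drying constant, 9-model
ranking, diffusivity), groups curves by pressure for Arrhenius and
thermodynamics (skipped with a warning below two temperatures), and
evaluates the economic scenario per curve using the curve's final time
as the batch time. Stage failures are isolated per curve/model. The
report is plain-dict JSON and round-trips losslessly; given the same
inputs and seed it is byte-identical.

Statistical calibration in the test suite uses 200 replicates for the
rate-constant recovery studies and 60 for standard-error coverage —
sizes at which the binomial noise on the checked quantiles is well
inside the asserted margins while the whole suite stays desk-scale.
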