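"""Thin-layer drying model bank and nonlinear fitting.

Nine closed-form moisture-ratio models commonly used for thin-layer
drying (Page, Midilli family, logarithmic, Wang–Singh, Weibull forms,
Aghbashlo) are fitted by nonlinear least squares, with goodness-of-fit
statistics using an n − p degrees-of-freedom convention throughout:
RMSE = sqrt(SSE/(n−p)), adjusted R² with (n−1)/(n−p), and parameter
p-values from two-sided t statistics on n − p dof.

The Page and Weibull parameterizations are algebraically equivalent;
:func:`page_weibull_equivalents` converts between them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats

from .curves import DryingCurve

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ExponentialFit",
    "MODELS",
    "get_model",
    "predict_mr",
    "fit_model",
    "goodness_of_fit",
    "rank_models",
    "fit_drying_constant",
    "page_weibull_equivalents",
    "FitFailureError",
]

LN10 = math.log(10.0)


class FitFailureError(RuntimeError):
    """Raised when a nonlinear fit fails to converge after multi-start."""


@dataclass(frozen=True)
class ModelSpec:
    """A thin-layer model: closed form, parameter names, bounds, initializer."""

    model_id: str
    param_names: Tuple[str, ...]
    func: Callable[..., np.ndarray]
    lower: Tuple[float, ...]
    upper: Tuple[float, ...]
    # initializer maps a rough exponential rate constant k0 to a start vector
    init: Callable[[float], Tuple[float, ...]]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _aghbashlo(t, k1, k2):
    # clamp the exponent: optimizer excursions with k2 < 0 can push the
    # denominator through zero
    return np.exp(np.clip(-k1 * t / (1.0 + k2 * t), -700.0, 50.0))


def _logarithmic(t, a, k, c):
    return a * np.exp(-k * t) + c


def _midilli(t, a, k, n, b):
    return a * np.exp(-k * np.power(t, n)) + b * t


def _modified_midilli_1(t, k, n, b):
    return np.exp(-k * np.power(t, n)) + b * t


def _modified_midilli_2(t, a, k, n, b):
    return a * np.exp(-k * np.power(t, n)) + b


def _page(t, k, n):
    return np.exp(-k * np.power(t, n))


def _wang_singh(t, a, b):
    return 1.0 + b * t + a * t * t


def _weibullian(t, alpha, beta):
    return np.exp(-np.power(t / alpha, beta))


def _weibullian_1(t, delta, n):
    return np.power(10.0, -np.power(t / delta, n))


_POS = 1e-8
_INF = np.inf

MODELS: Dict[str, ModelSpec] = {
    s.model_id: s
    for s in [
        ModelSpec(
            "aghbashlo", ("k1", "k2"), _aghbashlo,
            (_POS, -_INF), (_INF, _INF),
            lambda k0: (k0, 0.0),
        ),
        ModelSpec(
            "logarithmic", ("a", "k", "c"), _logarithmic,
            (0.0, _POS, -_INF), (2.0, _INF, _INF),
            lambda k0: (1.0, k0, 0.0),
        ),
        ModelSpec(
            "midilli", ("a", "k", "n", "b"), _midilli,
            (0.0, _POS, 0.05, -_INF), (2.0, _INF, 5.0, _INF),
            lambda k0: (1.0, k0, 1.0, 0.0),
        ),
        ModelSpec(
            "modified_midilli_1", ("k", "n", "b"), _modified_midilli_1,
            (_POS, 0.05, -_INF), (_INF, 5.0, _INF),
            lambda k0: (k0, 1.0, 0.0),
        ),
        ModelSpec(
            "modified_midilli_2", ("a", "k", "n", "b"), _modified_midilli_2,
            (0.0, _POS, 0.05, -_INF), (2.0, _INF, 5.0, _INF),
            lambda k0: (1.0, k0, 1.0, 0.0),
        ),
        ModelSpec(
            "page", ("k", "n"), _page,
            (_POS, 0.05), (_INF, 5.0),
            lambda k0: (k0, 1.0),
        ),
        ModelSpec(
            "wang_singh", ("a", "b"), _wang_singh,
            (-_INF, -_INF), (_INF, _INF),
            lambda k0: (0.0, -k0),
        ),
        ModelSpec(
            "weibullian", ("alpha", "beta"), _weibullian,
            (_POS, 0.05), (_INF, 5.0),
            lambda k0: (1.0 / max(k0, _POS), 1.0),
        ),
        ModelSpec(
            "weibullian_1", ("delta", "n"), _weibullian_1,
            (_POS, 0.05), (_INF, 5.0),
            lambda k0: (LN10 / max(k0, _POS), 1.0),
        ),
    ]
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; choose from {sorted(MODELS)}"
        ) from None


ParamsLike = Union[Sequence[float], Mapping[str, float]]


def _param_vector(spec: ModelSpec, params: ParamsLike) -> np.ndarray:
    if isinstance(params, Mapping):
        return np.array([params[name] for name in spec.param_names], dtype=float)
    vec = np.asarray(params, dtype=float)
    if vec.size != spec.n_params:
        raise ValueError(f"{spec.model_id} expects {spec.n_params} parameters")
    return vec


def predict_mr(model: Union[str, ModelSpec], params: ParamsLike, t) -> np.ndarray:
    """Evaluate a model's closed-form MR(t; θ); vectorizes over t (minutes)."""
    spec = get_model(model) if isinstance(model, str) else model
    vec = _param_vector(spec, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("drying time must be non-negative")
    if spec.model_id in ("weibullian", "weibullian_1") and vec[0] <= 0:
        raise ValueError("Weibull scale parameter must be positive")
    return spec.func(t, *vec)


@dataclass(frozen=True)
class ModelFit:
    """A fitted thin-layer model with its significance statistics."""

    model_id: str
    params: Dict[str, float]
    std_errors: Dict[str, float]
    p_values: Dict[str, float]
    significant: Dict[str, bool]
    rmse: float
    r_squared: float
    adj_r_squared: float
    fitted: np.ndarray
    n_obs: int
    n_params: int
    sse: float
    converged: bool = True
    message: str = ""

    def param_vector(self) -> np.ndarray:
        return np.array(list(self.params.values()), dtype=float)


def goodness_of_fit(observed, fitted, n_params: int) -> Dict[str, float]:
    """R², adjusted R² and RMSE with an n − p dof convention.

    R² = 1 − SSE/SST;  adjR² = 1 − (1−R²)(n−1)/(n−p);
    RMSE = sqrt(SSE/(n−p)).
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    n = obs.size
    p = int(n_params)
    if n <= p:
        raise ValueError("need more data points than parameters")
    sse = float(np.sum((obs - fit) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ZeroDivisionError("constant observed sequence: R² undefined")
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    rmse = math.sqrt(sse / (n - p))
    return {"r_squared": r2, "adj_r_squared": adj, "rmse": rmse, "sse": sse}


@dataclass(frozen=True)
class ExponentialFit:
    """Log-linear fit MR = A·exp(−k t): drying constant k in min⁻¹."""

    k: float
    A: float
    r_squared: float
    n_used: int

    @property
    def slope(self) -> float:
        return -self.k

    @property
    def intercept(self) -> float:
        return math.log(self.A)


def fit_drying_constant(curve: DryingCurve) -> ExponentialFit:
    """Drying constant from OLS of ln MR on time.

    Points with MR ≤ 0 (noise tail) are excluded from the log-domain
    regression; at least 3 usable points are required.  Slope = −k,
    intercept = ln A; R² is that of the log-domain regression.
    """
    if curve.moisture_ratio is None:
        raise ValueError("curve has no moisture-ratio trace; derive it first")
    mr = curve.moisture_ratio
    mask = mr > 0
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points with MR > 0")
    res = stats.linregress(curve.times_min[mask], np.log(mr[mask]))
    return ExponentialFit(
        k=-float(res.slope),
        A=float(math.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        n_used=int(mask.sum()),
    )


def _initial_rate(curve: DryingCurve) -> float:
    """Rough exponential rate used to seed nonlinear fits."""
    try:
        return max(fit_drying_constant(curve).k, _POS)
    except ValueError:
        # fall back to a half-life guess from the time axis
        return math.log(2.0) / max(curve.times_min[-1] / 2.0, 1.0)


def fit_model(
    model: Union[str, ModelSpec],
    curve: DryingCurve,
    n_starts: int = 5,
    alpha: float = 0.05,
) -> ModelFit:
    """Nonlinear least-squares fit of one thin-layer model to a curve.

    The start point seeds rate-like parameters from the log-linear
    drying constant; up to ``n_starts`` deterministically jittered
    restarts run before declaring failure.  Standard errors come from
    the Jacobian-based covariance at the optimum (residual variance
    SSE/(n−p)); p-values are two-sided t tests on n − p dof.
    """
    spec = get_model(model) if isinstance(model, str) else model
    if curve.moisture_ratio is None:
        raise ValueError("curve has no moisture-ratio trace; derive it first")
    t = curve.times_min
    mr = curve.moisture_ratio
    n, p = t.size, spec.n_params
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} points to fit {spec.model_id}")

    k0 = _initial_rate(curve)
    base = np.array(spec.init(k0), dtype=float)
    lo = np.array(spec.lower)
    hi = np.array(spec.upper)
    base = np.clip(base, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, base))

    rng = np.random.default_rng(0)  # jitter is deterministic by design
    best: Optional[Tuple[np.ndarray, Optional[np.ndarray], float]] = None
    last_err = ""
    for trial in range(n_starts):
        x0 = base if trial == 0 else base * rng.lognormal(0.0, 0.3, size=p) + rng.normal(
            0.0, 0.01, size=p
        )
        x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x0))
        try:
            popt, pcov = optimize.curve_fit(
                spec.func, t, mr, p0=x0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:  # non-convergence
            last_err = str(exc)
            continue
        sse = float(np.sum((mr - spec.func(t, *popt)) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitFailureError(
            f"{spec.model_id}: no convergence after {n_starts} starts ({last_err})"
        )

    popt, pcov, sse = best
    fitted = spec.func(t, *popt)
    gof = goodness_of_fit(mr, fitted, p)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov)) if pcov is not None else np.full(p, np.nan)
    dof = n - p
    tstat = np.divide(popt, se, out=np.full(p, np.nan), where=np.isfinite(se) & (se > 0))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    names = spec.param_names
    return ModelFit(
        model_id=spec.model_id,
        params={nm: float(v) for nm, v in zip(names, popt)},
        std_errors={nm: float(v) for nm, v in zip(names, se)},
        p_values={nm: float(v) for nm, v in zip(names, pvals)},
        significant={nm: bool(v <= alpha) for nm, v in zip(names, pvals)},
        rmse=gof["rmse"],
        r_squared=gof["r_squared"],
        adj_r_squared=gof["adj_r_squared"],
        fitted=fitted,
        n_obs=n,
        n_params=p,
        sse=gof["sse"],
    )


def rank_models(fits: Sequence[ModelFit]) -> list:
    """Order fits by goodness: ascending RMSE, then descending adjusted
    R², then fewer parameters (parsimony tie-break)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(fits, key=lambda f: (f.rmse, -f.adj_r_squared, f.n_params))


def page_weibull_equivalents(k: float, n: float) -> Dict[str, float]:
    """Exact parameter conversions within the Page/Weibull family.

    Page exp(−k tⁿ) ≡ Weibull exp(−(t/α)^β) with β = n, α = k^(−1/n),
    and ≡ the base-10 form 10^(−(t/δ)ⁿ) with δ = α·(ln 10)^(1/n).
    Pure algebra, no fitting.
    """
    if k <= 0 or n <= 0:
        raise ValueError("k and n must be positive")
    alpha = k ** (-1.0 / n)
    return {"alpha": alpha, "beta": n, "delta": alpha * LN10 ** (1.0 / n)}
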