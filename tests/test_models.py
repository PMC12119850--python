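"""Thin-layer model bank: closed forms, fitting, statistics, algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vacudry import (
    MODELS,
    Conditions,
    DryingCurve,
    GeneratorSpec,
    fit_drying_constant,
    fit_model,
    generate_curve,
    goodness_of_fit,
    moisture_ratio_series,
    page_weibull_equivalents,
    predict_mr,
    rank_models,
)


def mr_curve(times, mr, temp=50.0):
    return DryingCurve(
        times_min=np.asarray(times, float),
        conditions=Conditions(temperature_C=temp),
        moisture_ratio=np.asarray(mr, float),
    )


def page_curve(k=0.02, n=0.9, t_max=510.0, step=15.0):
    t = np.arange(0.0, t_max + step / 2, step)
    return mr_curve(t, np.exp(-k * t**n))


class TestPredict:
    def test_unit_start(self):
        assert predict_mr("page", {"k": 0.09174, "n": 0.81831}, 0.0) == pytest.approx(1.0)

    def test_weibull_characteristic_time(self):
        mr = predict_mr("weibullian", {"alpha": 116.70, "beta": 0.80779}, 116.70)
        assert mr == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_page_weibull_numerical_agreement(self):
        # independently fitted parameterizations of the same kinetics
        t = np.array([30.0, 120.0, 300.0])
        page = predict_mr("page", {"k": 0.02139, "n": 0.80779}, t)
        weib = predict_mr("weibullian", {"alpha": 116.70, "beta": 0.80779}, t)
        assert np.all(np.abs(page - weib) < 1e-3)

    def test_unknown_model_and_bad_scale(self):
        with pytest.raises(KeyError):
            predict_mr("nonesuch", [1.0], 0.0)
        with pytest.raises(ValueError):
            predict_mr("weibullian", {"alpha": -1.0, "beta": 1.0}, 10.0)

    @settings(derandomize=True, deadline=None)
    @given(
        st.floats(1e-3, 0.2), st.floats(0.3, 2.0), st.floats(0.0, 500.0)
    )
    def test_three_parameterizations_point_identical(self, k, n, t):
        eq = page_weibull_equivalents(k, n)
        p = predict_mr("page", {"k": k, "n": n}, t)
        w = predict_mr("weibullian", {"alpha": eq["alpha"], "beta": eq["beta"]}, t)
        w1 = predict_mr("weibullian_1", {"delta": eq["delta"], "n": n}, t)
        assert p == pytest.approx(w, abs=1e-12)
        assert p == pytest.approx(w1, abs=1e-12)


class TestPageWeibullEquivalents:
    @pytest.mark.parametrize(
        "k,n,alpha,delta",
        [
            (0.02139, 0.80779, 116.70, 327.68),
            (0.09174, 0.81831, 18.525, 51.33),
            (0.01, 1.0, 100.0, 230.2585),
        ],
    )
    def test_conversions(self, k, n, alpha, delta):
        eq = page_weibull_equivalents(k, n)
        assert eq["alpha"] == pytest.approx(alpha, rel=5e-4)
        assert eq["delta"] == pytest.approx(delta, rel=5e-4)
        assert eq["beta"] == n

    def test_positive_domain(self):
        with pytest.raises(ValueError):
            page_weibull_equivalents(-0.01, 1.0)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        g = goodness_of_fit([1, 0.5, 0.2], [1, 0.5, 0.2], 1)
        assert g["r_squared"] == 1.0 and g["rmse"] == 0.0

    def test_hand_arithmetic(self):
        g = goodness_of_fit([1, 0.5, 0.0], [1, 0.4, 0.0], 1)
        assert g["sse"] == pytest.approx(0.01)
        assert g["rmse"] == pytest.approx(np.sqrt(0.01 / 2), abs=1e-6)
        assert g["r_squared"] == pytest.approx(1 - 0.01 / 0.5)

    def test_adjusted_r2_formula(self):
        # back out adjR2 at n=10, p=2 from a constructed R2 of 0.99
        obs = np.linspace(1, 0, 10)
        sst = np.sum((obs - obs.mean()) ** 2)
        resid = np.sqrt(0.01 * sst / 10)
        fitted = obs + resid * np.where(np.arange(10) % 2 == 0, 1, -1)
        g = goodness_of_fit(obs, fitted, 2)
        assert g["r_squared"] == pytest.approx(0.99)
        assert g["adj_r_squared"] == pytest.approx(0.98875)

    def test_constant_observed_undefined(self):
        with pytest.raises(ZeroDivisionError):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 0.9, 1.0], 1)

    @settings(derandomize=True, deadline=None)
    @given(st.integers(4, 30))
    def test_extra_parameter_never_raises_adj_r2(self, n):
        rng = np.random.default_rng(n)
        obs = np.exp(-0.02 * np.arange(n) * 15.0) + rng.normal(0, 0.01, n)
        fitted = np.exp(-0.02 * np.arange(n) * 15.0)
        g1 = goodness_of_fit(obs, fitted, 1)
        g2 = goodness_of_fit(obs, fitted, 2)
        assert g2["adj_r_squared"] <= g1["adj_r_squared"] + 1e-15
        assert g1["adj_r_squared"] <= g1["r_squared"] + 1e-15


class TestFitModel:
    def test_noiseless_page_round_trip(self):
        fit = fit_model("page", page_curve())
        assert fit.params["k"] == pytest.approx(0.02, abs=1e-6)
        assert fit.params["n"] == pytest.approx(0.9, abs=1e-6)
        assert fit.rmse < 1e-8

    def test_weibull_recovers_equivalent_scale(self):
        fit = fit_model("weibullian", page_curve())
        assert fit.params["alpha"] == pytest.approx(0.02 ** (-1 / 0.9), abs=1e-4)

    def test_all_models_fit_and_page_family_ranks_first(self):
        curve = page_curve()
        fits = [fit_model(mid, curve) for mid in sorted(MODELS)]
        ranked = rank_models(fits)
        # the generating family (Page and its reparameterizations /
        # supersets) must beat the structurally wrong Wang-Singh form
        wang = next(f for f in ranked if f.model_id == "wang_singh")
        assert ranked[0].rmse <= wang.rmse
        assert ranked[0].model_id != "wang_singh"
        for f in fits:
            assert f.adj_r_squared <= f.r_squared + 1e-15
            assert f.sse == pytest.approx(f.rmse**2 * (f.n_obs - f.n_params), rel=1e-9)

    def test_unit_start_models_fitted_trace(self):
        curve = page_curve()
        for mid in ("page", "weibullian", "weibullian_1", "aghbashlo", "wang_singh"):
            fit = fit_model(mid, curve)
            assert abs(fit.fitted[0] - 1.0) < 1e-9

    def test_statistics_significant_on_clean_data(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 511, 15.0)
        mr = np.exp(-0.02 * t**0.9) + rng.normal(0, 0.01, t.size)
        fit = fit_model("page", mr_curve(t, mr))
        assert all(fit.significant.values())
        assert all(se > 0 for se in fit.std_errors.values())
        assert fit.p_values["k"] < 0.05

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_model("midilli", mr_curve([0, 15, 30], [1.0, 0.8, 0.6]))

    def test_grid_search_oracle_matches_optimizer_sse(self):
        # brute-force refinement over the (k, n) box as an independent
        # optimum check on a short noisy curve
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 436, 15.0)  # 30 points
        mr = np.exp(-0.02 * t**0.9) + rng.normal(0, 0.01, t.size)
        curve = mr_curve(t, mr)
        fit = fit_model("page", curve)

        def sse(k, n):
            return float(np.sum((mr - np.exp(-k * t**n)) ** 2))

        klo, khi, nlo, nhi = 1e-3, 0.2, 0.3, 2.0
        for _ in range(3):  # initial pass + two refinements
            kk = np.linspace(klo, khi, 60)
            nn = np.linspace(nlo, nhi, 60)
            vals = np.array([[sse(k, n) for n in nn] for k in kk])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            dk, dn = (khi - klo) / 10, (nhi - nlo) / 10
            klo, khi = max(kk[i] - dk, 1e-6), kk[i] + dk
            nlo, nhi = max(nn[j] - dn, 0.05), nn[j] + dn
        assert vals.min() <= fit.sse * 1.001
        assert fit.sse <= vals.min() * 1.001

    def test_noisy_replicates_cover_truth_within_3_se(self):
        # weight-domain noise at a 0.01 MR-equivalent level
        sd = 0.01 * 14.5 * (0.855 / 0.145 - 0.134 / 0.866)
        spec = GeneratorSpec(
            true_params={(50.0, -5.0): {"k": 0.02, "n": 0.9}},
            noise_sd_g=sd,
            mr_stop=1e-9,
        )
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            c = generate_curve(spec, (50.0, -5.0), rng=rng)
            fit = fit_model("page", moisture_ratio_series(c, use_equilibrium=True))
            if abs(fit.params["k"] - 0.02) <= 3 * fit.std_errors["k"]:
                hits += 1
        assert hits / n_rep >= 0.90


class TestRankModels:
    def make_fit(self, model_id, rmse, adj, p):
        from vacudry.models import ModelFit

        return ModelFit(
            model_id=model_id,
            params={},
            std_errors={},
            p_values={},
            significant={},
            rmse=rmse,
            r_squared=adj,
            adj_r_squared=adj,
            fitted=np.array([1.0]),
            n_obs=10,
            n_params=p,
            sse=rmse**2 * (10 - p),
        )

    def test_rmse_orders_first(self):
        page = self.make_fit("page", 0.004, 0.999, 2)
        wang = self.make_fit("wang_singh", 0.08, 0.88, 2)
        assert rank_models([wang, page])[0].model_id == "page"

    def test_parsimony_tie_break(self):
        a = self.make_fit("midilli", 0.01, 0.99, 4)
        b = self.make_fit("page", 0.01, 0.99, 2)
        assert rank_models([a, b])[0].model_id == "page"

    def test_single_and_empty(self):
        only = self.make_fit("page", 0.01, 0.99, 2)
        assert rank_models([only]) == [only]
        with pytest.raises(ValueError):
            rank_models([])


class TestDryingConstant:
    def test_exact_exponential(self):
        t = np.arange(0.0, 511, 15.0)
        fit = fit_drying_constant(mr_curve(t, np.exp(-0.0164 * t)))
        assert fit.k == pytest.approx(0.0164, rel=1e-12)
        assert fit.A == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_prefactor_recovery(self):
        t = np.arange(0.0, 511, 15.0)
        fit = fit_drying_constant(mr_curve(t, 0.95 * np.exp(-0.02 * t)))
        assert fit.A == pytest.approx(0.95, rel=1e-10)
        assert fit.k == pytest.approx(0.02, rel=1e-10)

    def test_nonpositive_tail_dropped(self):
        t = np.arange(6) * 15.0
        mr = np.array([1.0, 0.5, 0.25, 0.125, 0.0, -0.01])
        fit = fit_drying_constant(mr_curve(t, mr))
        assert np.isfinite(fit.k) and fit.k > 0
        assert fit.n_used == 4

    def test_too_few_usable_points(self):
        with pytest.raises(ValueError):
            fit_drying_constant(mr_curve([0, 15, 30], [1.0, 0.0, -0.1]))
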