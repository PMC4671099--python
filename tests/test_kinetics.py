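"""Arrhenius rate law, labile-fraction decay, and the temperature score."""

import math

import numpy as np
import pytest

import poctherm as pt
from poctherm.kinetics import PredictedPOCCurve, temperature_score


def direct_rate(A, Ea, R, T_k):
    """Independent direct evaluation of the Arrhenius law (math module)."""
    return A * math.exp(-Ea / (R * T_k))


class TestRateConstant:
    @pytest.mark.parametrize("T_k", [275.15, 303.15, 290.0])
    def test_matches_direct_evaluation(self, default_params, T_k):
        p = default_params
        expected = direct_rate(p.A, p.Ea, p.R, T_k)
        assert pt.rate_constant(p, T_k) == pytest.approx(expected, rel=1e-12)

    def test_cold_and_warm_magnitudes(self, default_params):
        # ~3.93e-3 /Ma at 2 degC vs ~0.333 /Ma at 30 degC: degradation is
        # negligible over 10 Ma at cold sites and nearly complete at warm ones
        assert pt.rate_constant(default_params, 275.15) == pytest.approx(3.9256e-3, rel=1e-4)
        assert pt.rate_constant(default_params, 303.15) == pytest.approx(0.33323, rel=1e-4)

    def test_strictly_increasing_in_temperature(self, default_params):
        T = np.linspace(270.0, 400.0, 200)
        k = pt.rate_constant(default_params, T)
        assert np.all(np.diff(k) > 0)

    def test_zero_prefactor(self):
        p = pt.ArrheniusParams(A=0.0)
        assert pt.rate_constant(p, 300.0) == 0.0

    def test_nonpositive_temperature_rejected(self, default_params):
        with pytest.raises(ValueError):
            pt.rate_constant(default_params, 0.0)


class TestIntegrateG:
    @pytest.mark.parametrize("temp_c, age", [(2.0, 10.0), (30.0, 10.0), (15.0, 3.0)])
    def test_constant_temperature_matches_closed_form(
        self, simple_model, flat_geotherm, default_params, temp_c, age
    ):
        h = pt.burial_temperature_history(simple_model, flat_geotherm(temp_c), age, n_steps=200)
        k = direct_rate(default_params.A, default_params.Ea, default_params.R, temp_c + 273.15)
        expected = math.exp(-k * age)
        assert pt.integrate_G(h, default_params) == pytest.approx(expected, rel=1e-6)

    def test_warm_site_ten_ma(self, simple_model, flat_geotherm, default_params):
        h = pt.burial_temperature_history(simple_model, flat_geotherm(30.0), 10.0)
        assert pt.integrate_G(h, default_params) == pytest.approx(0.0357, abs=2e-4)

    def test_zero_age_returns_initial_fraction(self, simple_model, flat_geotherm, default_params):
        h = pt.burial_temperature_history(simple_model, flat_geotherm(30.0), 0.0)
        assert pt.integrate_G(h, default_params, G0=0.7) == 0.7

    def test_hotter_history_degrades_more(self, simple_model, default_params):
        g = [
            pt.integrate_G(
                pt.burial_temperature_history(simple_model, pt.GeothermFit("S", sft, 0.05, 1, 3), 5.0),
                default_params,
            )
            for sft in (2.0, 10.0, 20.0)
        ]
        assert g[0] > g[1] > g[2]


class TestPredictedCurve:
    def test_cold_flat_site_curve(self, simple_model, default_params):
        fit = pt.GeothermFit("SIMPLE", 2.0, 0.0, 1.0, 3)
        curve = pt.predicted_poc_curve(simple_model, fit, default_params)
        assert curve.G[0] == 1.0
        k = direct_rate(default_params.A, default_params.Ea, default_params.R, 275.15)
        np.testing.assert_allclose(curve.G, np.exp(-k * curve.ages), rtol=1e-6)
        assert curve.G[-1] == pytest.approx(0.96, abs=0.005)

    def test_hot_fast_site_destroys_labile_carbon(self, default_params):
        model = pt.AgeModel.from_nodes("HOT", [0.0, 3000.0], [0.0, 10.0])  # 300 m/Ma
        fit = pt.GeothermFit("HOT", 2.0, 0.09, 1.0, 3)
        curve = pt.predicted_poc_curve(model, fit, default_params)
        assert curve.G[-1] < 0.05

    def test_curve_nonincreasing_and_bounded(self, kinked_model, default_params):
        fit = pt.GeothermFit("KINK", 2.67, 0.053, 1.0, 3)
        curve = pt.predicted_poc_curve(kinked_model, fit, default_params)
        assert np.all(np.diff(curve.G) <= 0)
        assert np.all((curve.G >= 0) & (curve.G <= 1))
        assert 0 <= curve.score <= 1

    def test_age_grid_includes_both_endpoints(self, simple_model, default_params):
        fit = pt.GeothermFit("SIMPLE", 2.0, 0.05, 1.0, 3)
        curve = pt.predicted_poc_curve(simple_model, fit, default_params)
        assert curve.ages[0] == 0.0 and curve.ages[-1] == 10.0
        assert curve.ages.size == 100

    def test_halving_time_step_barely_moves_score(self, kinked_model, default_params):
        fit = pt.GeothermFit("KINK", 2.67, 0.08, 1.0, 3)
        s200 = pt.predicted_poc_curve(kinked_model, fit, default_params, n_steps=200).score
        s400 = pt.predicted_poc_curve(kinked_model, fit, default_params, n_steps=400).score
        assert abs(s200 - s400) < 1e-4


class TestTemperatureScore:
    def test_no_degradation_limit(self):
        ages = np.linspace(0, 10, 100)
        assert temperature_score(PredictedPOCCurve("X", ages, np.ones(100))) == 0.0

    def test_instant_degradation_limit(self):
        ages = np.linspace(0, 10, 100)
        assert temperature_score(PredictedPOCCurve("X", ages, np.zeros(100))) == 1.0

    def test_exponential_curve_against_analytic_integral(self):
        ages = np.linspace(0, 10, 100)
        k = 0.333
        G = np.exp(-k * ages)
        s = temperature_score(PredictedPOCCurve("X", ages, G))
        analytic = 1 - (1 - math.exp(-10 * k)) / (10 * k)  # integral of e^{-kt}/10
        assert s == pytest.approx(analytic, abs=1e-3)
        assert s == pytest.approx(0.710, abs=2e-3)

    def test_strictly_decreasing_in_curve_integral(self, rng):
        ages = np.linspace(0, 10, 100)
        pairs = []
        for _ in range(50):
            G = np.minimum.accumulate(rng.uniform(0, 1, 100))
            G[0] = 1.0
            pairs.append((np.trapezoid(G, ages), temperature_score(PredictedPOCCurve("X", ages, G))))
        pairs.sort()
        scores = [s for _, s in pairs]
        assert all(a > b for a, b in zip(scores, scores[1:]))


def test_score_ordering_insensitive_to_activation_energy(rng):
    """Halving/doubling Ea preserves the ranking of non-crossing histories."""
    gradients = rng.uniform(0.02, 0.12, 12)
    model = pt.AgeModel.from_nodes("E", [0.0, 1000.0], [0.0, 10.0])
    orders = []
    k_ref, t_ref = 0.05, 283.15  # pin k at 10 degC so curves stay in range
    for ea in (55_000.0, 110_000.0, 220_000.0):
        A = k_ref / math.exp(-ea / (8.314 * t_ref))
        params = pt.ArrheniusParams(A=A, Ea=ea)
        scores = [
            pt.predicted_poc_curve(model, pt.GeothermFit("E", 2.0, g, 1.0, 3), params).score
            for g in gradients
        ]
        orders.append(np.argsort(scores).tolist())
    assert orders[0] == orders[1] == orders[2]
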