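"""TPC model functions, weighted fitting, bootstrap and AIC selection."""

import numpy as np
import pandas as pd
import pytest

from snowmotility.simulate import simulate_tpc_dataset
from snowmotility.tpc import (
    K_BOLTZ,
    PawarParams,
    ThermalPerformanceModel,
    Thomas2Params,
    WeibullParams,
    derive_topt_rmax,
    fit_tpc,
    model_select_aic,
    pawar_rate,
    thomas2_rate,
    weibull_rate,
)


def _pawar_reference(temp, r_tref, e, eh, topt, tref=1.0):
    """Independent transcription of the Sharpe–Schoolfield-type curve,
    assembled term by term with math-module scalars."""
    import math

    tk = temp + 273.15
    trefk = tref + 273.15
    toptk = topt + 273.15
    numerator = r_tref * math.exp(-(e / K_BOLTZ) * (1.0 / tk - 1.0 / trefk))
    inactivation = (e / (eh - e)) * math.exp((eh / K_BOLTZ) * (1.0 / toptk - 1.0 / tk))
    return numerator / (1.0 + inactivation)


class TestModelFunctions:
    def test_pawar_matches_independent_transcription(self):
        for t in np.linspace(-2, 32, 35):
            expected = _pawar_reference(float(t), 30.0, 0.6, 4.0, 8.0)
            assert pawar_rate(t, 30.0, 0.6, 4.0, 8.0) == pytest.approx(expected, rel=1e-10)

    def test_pawar_reduces_to_arrhenius_for_huge_eh(self):
        # far below the optimum with enormous inactivation energy the
        # denominator is 1 and the curve is pure Boltzmann-Arrhenius
        t = 3.0
        arrhenius = 30.0 * np.exp(
            -0.6 / K_BOLTZ * (1 / (t + 273.15) - 1 / (1.0 + 273.15))
        )
        assert pawar_rate(t, 30.0, 0.6, 1e4, 20.0) == pytest.approx(arrhenius, rel=1e-6)

    def test_pawar_peak_sits_at_topt_parameter(self):
        p = PawarParams(r_tref=30.0, e_act=0.6, eh=4.0, topt=8.0)
        topt_num, _ = derive_topt_rmax(p.rate, (0.0, 30.0), grid_step=0.001)
        assert topt_num == pytest.approx(8.0, abs=0.01)

    def test_pawar_invariant_validation(self):
        with pytest.raises(ValueError):
            PawarParams(r_tref=30.0, e_act=2.0, eh=1.0, topt=8.0)

    def test_thomas2_without_inactivation_is_pure_exponential(self):
        t = np.linspace(0, 30, 13)
        vals = thomas2_rate(t, 40.0, 0.08, 0.0, 0.0, 0.3)
        assert np.allclose(vals, 40.0 * np.exp(0.08 * t))
        assert (np.diff(vals) > 0).all()

    def test_thomas2_intercept_is_rate_at_zero_celsius(self):
        assert thomas2_rate(0.0, 40.0, 0.08, 0.0, 0.0, 0.3) == pytest.approx(40.0)

    def test_thomas2_optimum_matches_stationary_point(self):
        a, b, c, d, e = 40.0, 0.08, 5.0, 1.0, 0.3
        # a b e^{bT} = d e e^{eT}  =>  T* = ln(ab/(de)) / (e - b)
        t_star = np.log(a * b / (d * e)) / (e - b)
        p = Thomas2Params(a, b, c, d, e)
        topt_num, _ = derive_topt_rmax(p.rate, (0.0, 30.0), grid_step=0.001)
        assert topt_num == pytest.approx(t_star, abs=0.01)

    def test_weibull_maximum_is_a_at_topt(self):
        p = WeibullParams(a=50.0, topt=10.0, b=15.0, c=3.0)
        topt_num, rmax = derive_topt_rmax(p.rate, (0.0, 30.0), grid_step=0.001)
        assert topt_num == pytest.approx(10.0, abs=0.01)
        assert rmax == pytest.approx(50.0, rel=1e-4)
        assert np.all(np.isfinite(weibull_rate(np.linspace(-50, 50, 101), 50, 10, 15, 3)))


class TestFitting:
    def test_noiseless_thomas2_recovery(self):
        p = Thomas2Params(40.0, 0.08, 5.0, 1.0, 0.3)
        t = np.array([0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5])
        rates = p.rate(t)
        df = pd.DataFrame({"temperature_C": t, "rate": rates, "sd": 1.0, "n": 3})
        res = fit_tpc(df, "thomas2", n_boot=0)
        true_topt, _ = derive_topt_rmax(p.rate, (0.0, 17.5))
        assert res.topt_C == pytest.approx(true_topt, abs=0.1)

    def test_zero_bootstrap_gives_point_estimates_only(self):
        p = PawarParams(30.0, 0.6, 4.0, 8.0)
        df = simulate_tpc_dataset(p, seed=1)
        res = fit_tpc(df, "pawar", n_boot=0)
        assert np.isfinite(res.topt_C) and np.isfinite(res.rmax)
        assert np.isnan(res.ci_topt[0]) and np.isnan(res.ci_rmax[1])
        assert res.boot_topt.size == 0

    def test_bootstrap_reproducible_for_fixed_seed(self):
        p = PawarParams(30.0, 0.6, 4.0, 8.0)
        df = simulate_tpc_dataset(p, seed=2)
        r1 = fit_tpc(df, "pawar", n_boot=30, seed=99)
        r2 = fit_tpc(df, "pawar", n_boot=30, seed=99)
        assert np.array_equal(r1.boot_topt, r2.boot_topt)
        assert r1.ci_topt == r2.ci_topt

    def test_rmax_attained_inside_search_range(self):
        p = Thomas2Params(40.0, 0.08, 5.0, 0.3, 0.25)
        df = simulate_tpc_dataset(p, seed=3)
        res = fit_tpc(df, "thomas2", n_boot=0)
        lo = df["temperature_C"].min() - 2.0
        hi = df["temperature_C"].max() + 2.0
        assert lo < res.topt_C < hi
        assert res.rmax == pytest.approx(float(res.predict(res.topt_C)), rel=1e-6)

    def test_too_few_temperatures_raises(self):
        df = pd.DataFrame({"temperature_C": [0.0, 5.0, 10.0], "rate": [1.0, 2.0, 1.5],
                           "sd": [0.1] * 3, "n": [3] * 3})
        with pytest.raises(ValueError, match="distinct temperatures"):
            fit_tpc(df, "pawar")

    def test_all_zero_rates_raise(self):
        df = pd.DataFrame({"temperature_C": np.arange(8.0), "rate": np.zeros(8),
                           "sd": np.ones(8), "n": [3] * 8})
        with pytest.raises(ValueError, match="zero"):
            fit_tpc(df, "thomas2")

    def test_weighting_options(self):
        p = PawarParams(30.0, 0.6, 4.0, 8.0)
        df = simulate_tpc_dataset(p, seed=4)
        m_sd = ThermalPerformanceModel.from_dataframe(df, model="pawar", weights="inv_sd")
        m_var = ThermalPerformanceModel.from_dataframe(df, model="pawar", weights="inv_var")
        assert np.allclose(m_var._w, m_sd._w**2)
        with pytest.raises(ValueError):
            ThermalPerformanceModel.from_dataframe(df.assign(sd=0.0), model="pawar")

    def test_summary_and_curve_outputs(self):
        p = PawarParams(30.0, 0.6, 4.0, 8.0)
        df = simulate_tpc_dataset(p, seed=5)
        res = fit_tpc(df, "pawar", n_boot=20, seed=0)
        text = res.summary()
        assert "T_opt" in text and "pawar" in text
        curve = res.curve(grid_step=0.5)
        assert (np.diff(curve["temperature_C"]) > 0).all()
        assert (curve["rate"] >= 0).all()
        d = res.to_dict()
        assert d["model"] == "pawar" and "eh" in d["params"]


class TestModelSelection:
    def test_lowest_aic_wins_and_ties_prefer_fewer_params(self):
        p = PawarParams(30.0, 0.6, 4.0, 8.0)
        df = simulate_tpc_dataset(p, seed=6)
        f_pawar = fit_tpc(df, "pawar", n_boot=0)
        f_weib = fit_tpc(df, "weibull", n_boot=0)
        best = model_select_aic([f_pawar, f_weib])
        assert best.aic == min(f_pawar.aic, f_weib.aic)
        # exact tie: duplicate fit objects with equal AIC
        import copy

        tie = copy.copy(f_pawar)
        tie.model = "thomas2"  # 5 params vs pawar's 4
        assert model_select_aic([tie, f_pawar]).model == "pawar"

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            model_select_aic([])
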