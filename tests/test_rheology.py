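"""Rheology: step viscosities, yield-stress fits, hysteresis loops."""

import numpy as np
import pandas as pd
import pytest

from semisolid.exceptions import InsufficientDataError, InvalidInputError
from semisolid.rheology import (
    FlowCurve,
    compare_thixotropy,
    fit_casson,
    hysteresis_area,
    summarize_step_viscosity,
    temperature_ratio,
)

from conftest import STEP_VISCOSITIES


def readings_frame(cells):
    """cells: list of (fid, temp, rate, [replicate viscosities])."""
    rows = [
        {"formulation_id": f, "temperature_C": t, "shear_rate_s1": r,
         "replicate": i, "viscosity_mPas": v}
        for f, t, r, vals in cells
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows)


def linear_flow_curve(tau_up, tau_down, rates=None, temperature=25.0):
    """Piecewise ramp with stress given by callables per phase."""
    if rates is None:
        rates = np.linspace(100.0, 1100.0, 41)
    rate = np.concatenate([rates, rates[::-1]])
    phase = np.array(["up"] * rates.size + ["down"] * rates.size, dtype=object)
    stress = np.concatenate([tau_up(rates), tau_down(rates[::-1])])
    return FlowCurve(rate, stress, phase, temperature_C=temperature)


class TestStepViscosity:
    def test_mean_sd(self):
        out = summarize_step_viscosity(
            readings_frame([("F-1", 25.0, 300.0, [1900.0, 1914.0]),
                            ("F-1", 25.0, 700.0, [1250.0, 1264.0]),
                            ("F-1", 25.0, 1100.0, [700.0, 714.0])])
        )
        row = out[out["shear_rate_s1"] == 300.0].iloc[0]
        assert row["mean"] == pytest.approx(1907.0)
        assert row["sd"] == pytest.approx(9.9, abs=0.05)
        assert row["n"] == 2
        assert bool(row["shear_thinning"])

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientDataError, match="replicate"):
            summarize_step_viscosity(
                readings_frame([("F-1", 25.0, 300.0, [1900.0])])
            )

    def test_identical_replicates_zero_sd(self):
        out = summarize_step_viscosity(
            readings_frame([("F-1", 25.0, 300.0, [500.0, 500.0, 500.0])])
        )
        assert out["sd"].iloc[0] == 0.0

    def test_temperature_ratio(self):
        cells = [
            (fid, temp, rate, [v, v])
            for fid, temps in STEP_VISCOSITIES.items()
            for temp, means in temps.items()
            for rate, v in zip((300.0, 700.0, 1100.0), means)
        ]
        table = summarize_step_viscosity(readings_frame(cells))
        # strong thinning with temperature at low rate for the plain base
        assert temperature_ratio(table, "F-1", 300.0) == pytest.approx(
            1907 / 754, rel=1e-9
        )
        # nearly temperature-insensitive regime at the top rate, high load
        assert temperature_ratio(table, "F-7", 1100.0) == pytest.approx(
            798 / 782, rel=1e-9
        )
        with pytest.raises(InvalidInputError):
            temperature_ratio(table, "F-1", 999.0)


class TestCassonFit:
    def test_linear_noiseless_recovery(self):
        curve = linear_flow_curve(
            lambda g: 5.0 + 0.002 * g, lambda g: 5.0 + 0.002 * g
        )
        fit = fit_casson(curve, variant="linear")
        assert fit.tau_y == pytest.approx(5.0, rel=1e-9)
        assert fit.eta == pytest.approx(0.002, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_newtonian_zero_yield(self):
        curve = linear_flow_curve(lambda g: 0.001 * g, lambda g: 0.001 * g)
        fit = fit_casson(curve)
        assert fit.tau_y == pytest.approx(0.0, abs=1e-9)

    def test_linear_equals_polyfit_ols(self):
        """The linear variant is exactly OLS of stress on rate."""
        rng = np.random.default_rng(7)
        rates = np.linspace(100.0, 1100.0, 30)
        stress = 8.0 + 0.004 * rates + rng.normal(0, 0.3, rates.size)
        curve = linear_flow_curve(
            lambda g: stress, lambda g: stress[::-1], rates=rates
        )
        slope, intercept = np.polyfit(rates, stress, 1)
        fit = fit_casson(curve, variant="linear")
        assert fit.eta == pytest.approx(slope, rel=1e-9)
        assert fit.tau_y == pytest.approx(intercept, rel=1e-9)

    def test_matches_grid_search_oracle(self):
        """Least-squares parameters agree with a brute-force SSE grid search."""
        rng = np.random.default_rng(11)
        rates = np.linspace(100.0, 1100.0, 50)
        stress = 6.0 + 0.003 * rates + rng.normal(0, 0.2, rates.size)
        curve = linear_flow_curve(lambda g: stress, lambda g: stress[::-1],
                                  rates=rates)
        fit = fit_casson(curve)
        tys = np.linspace(4.0, 8.0, 161)       # step 0.025 Pa
        etas = np.linspace(0.002, 0.004, 161)  # step 1.25e-5 Pa*s
        sse = np.array(
            [[np.sum((stress - ty - e * rates) ** 2) for e in etas] for ty in tys]
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        # the grid minimum sits within a couple of grid steps of the OLS
        # optimum (the SSE valley is tilted, so allow 2 steps per axis)
        assert fit.tau_y == pytest.approx(tys[i], abs=2 * 0.025)
        assert fit.eta == pytest.approx(etas[j], abs=2 * 1.25e-5)
        # and the OLS solution is at least as good as every grid point
        sse_fit = np.sum((stress - fit.tau_y - fit.eta * rates) ** 2)
        assert sse_fit <= sse.min() + 1e-9

    def test_sqrt_variant_recovery(self):
        """Square-root Casson data round-trips through the sqrt variant."""
        ty, eta = 4.0, 0.0015
        rates = np.linspace(100.0, 1100.0, 41)
        stress = (np.sqrt(ty) + np.sqrt(eta * rates)) ** 2
        curve = linear_flow_curve(lambda g: stress, lambda g: stress[::-1],
                                  rates=rates)
        fit = fit_casson(curve, variant="sqrt")
        assert fit.tau_y == pytest.approx(ty, rel=1e-6)
        assert fit.eta == pytest.approx(eta, rel=1e-6)

    def test_singular_design(self):
        rate = np.array([500.0] * 3 + [500.0] * 3)
        phase = np.array(["up"] * 3 + ["down"] * 3, dtype=object)
        curve = FlowCurve(rate, np.arange(6.0), phase)
        with pytest.raises(InvalidInputError, match="singular"):
            fit_casson(curve)


class TestHysteresis:
    def test_identical_curves_zero_area(self):
        curve = linear_flow_curve(lambda g: 2.0 + 0.01 * g,
                                  lambda g: 2.0 + 0.01 * g)
        assert hysteresis_area(curve) == pytest.approx(0.0, abs=1e-9)

    def test_rectangle_loop(self):
        """Constant 5 Pa offset over a 1000 1/s span -> 5000 Pa/s."""
        curve = linear_flow_curve(lambda g: 10.0 + 0.01 * g,
                                  lambda g: 5.0 + 0.01 * g)
        assert hysteresis_area(curve) == pytest.approx(5000.0, rel=1e-9)

    def test_antithixotropic_negative(self):
        curve = linear_flow_curve(lambda g: 5.0 + 0.01 * g,
                                  lambda g: 10.0 + 0.01 * g)
        assert hysteresis_area(curve) < 0

    def test_no_overlap_error(self):
        rate = np.array([100.0, 200.0, 300.0, 900.0, 800.0, 700.0])
        phase = np.array(["up"] * 3 + ["down"] * 3, dtype=object)
        curve = FlowCurve(rate, np.ones(6), phase)
        with pytest.raises(InvalidInputError, match="overlap"):
            hysteresis_area(curve)

    def test_resampling_invariance(self):
        """Denser sampling of a smooth loop changes the area < 0.5%."""

        def up(g):
            return 10.0 + 0.01 * g + 3.0 * np.sin(g / 400.0)

        def down(g):
            return 5.0 + 0.01 * g + 3.0 * np.sin(g / 400.0)

        coarse = linear_flow_curve(up, down, rates=np.linspace(100, 1100, 41))
        fine = linear_flow_curve(up, down, rates=np.linspace(100, 1100, 201))
        a, b = hysteresis_area(coarse), hysteresis_area(fine)
        assert abs(a - b) / abs(b) < 0.005


class TestCompareThixotropy:
    def test_ratio_and_flags(self):
        out = compare_thixotropy({"F-1": 5000.0}, {"F-1": 2500.0})
        row = out.iloc[0]
        assert row["ratio_hot_over_cold"] == pytest.approx(0.5)
        assert bool(row["smaller_when_hot"])

    def test_equal_areas_ratio_one(self):
        out = compare_thixotropy({"A": 100.0}, {"A": 100.0})
        assert out["ratio_hot_over_cold"].iloc[0] == pytest.approx(1.0)

    def test_known_ordering_recovered(self):
        cold = {"A": 3000.0, "B": 5000.0, "C": 1000.0}
        hot = {k: v / 2 for k, v in cold.items()}
        out = compare_thixotropy(cold, hot).set_index("formulation_id")
        assert out.loc["B", "rank_by_cold_area"] == 1
        assert out.loc["A", "rank_by_cold_area"] == 2
        assert out.loc["C", "rank_by_cold_area"] == 3

    def test_zero_cold_area_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = compare_thixotropy({"A": 0.0}, {"A": 10.0})
        assert np.isnan(out["ratio_hot_over_cold"].iloc[0])
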