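"""Release analysis: calibration, mass-balance correction, kinetic fits."""

import numpy as np
import pytest

from semisolid.exceptions import InsufficientDataError, InvalidInputError
from semisolid.release import (
    ReleaseExperiment,
    ReleaseProfile,
    absorbance_to_conc,
    compare_models,
    cumulative_release,
    fit_calibration,
    fit_release_model,
    release_law,
    release_rate_comparison,
)
from semisolid.simulate import gen_release_experiment

from conftest import CALIBRATION, CALIBRATION_CONCS, RELEASE_TIMES, VESSEL

SLOPE, INTERCEPT = CALIBRATION
TIMES = np.array(RELEASE_TIMES)


class TestCalibration:
    def test_noiseless_recovery(self):
        conc = np.array(CALIBRATION_CONCS)
        fit = fit_calibration(conc, SLOPE * conc + INTERCEPT)
        assert fit.slope == pytest.approx(SLOPE, rel=1e-9)
        assert fit.intercept == pytest.approx(INTERCEPT, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_photometric_noise_keeps_r2_high(self, seed):
        """+/- 0.005 A uniform noise on the 7-level design leaves R^2 >= 0.999."""
        rng = np.random.default_rng(seed)
        conc = np.array(CALIBRATION_CONCS)
        a = SLOPE * conc + INTERCEPT + rng.uniform(-0.005, 0.005, conc.size)
        assert fit_calibration(conc, a).r_squared >= 0.999

    def test_flat_absorbances_flagged(self):
        conc = np.array(CALIBRATION_CONCS)
        with pytest.warns(UserWarning, match="unusable"):
            fit = fit_calibration(conc, np.full(conc.size, 0.3))
        assert not fit.usable

    def test_single_level_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([0.5, 0.5], [0.27, 0.28])

    def test_inversion(self, calibration):
        assert absorbance_to_conc(0.5662, calibration) == pytest.approx(1.0, abs=1e-9)
        assert absorbance_to_conc(INTERCEPT, calibration) == pytest.approx(0.0)
        # forward-then-invert identity at 0.5 mg/mL
        a = INTERCEPT + SLOPE * 0.5
        assert absorbance_to_conc(a, calibration) == pytest.approx(0.5, rel=1e-12)

    def test_negative_floored(self, calibration):
        with pytest.warns(UserWarning, match="floored"):
            assert absorbance_to_conc(INTERCEPT - 0.1, calibration) == 0.0


def make_experiment(conc=None, times=TIMES, **kw):
    """Experiment whose absorbances encode the given vessel concentrations."""
    conc = np.zeros(times.size) if conc is None else np.asarray(conc)
    a = SLOPE * conc + INTERCEPT
    params = dict(VESSEL)
    params.update(kw)
    return ReleaseExperiment(times_min=times, absorbances=a[None, :], **params)


class TestCumulativeRelease:
    def test_single_point_hand_value(self):
        exp = make_experiment(times=np.array([15.0]))
        prof = cumulative_release([1.0], exp)
        assert prof.q_mg_cm2[0] == pytest.approx(50.0 / 3.8, rel=1e-9)
        assert prof.q_mg_cm2[0] == pytest.approx(13.158, abs=1e-3)

    def test_all_zero(self):
        prof = cumulative_release(np.zeros(6), make_experiment())
        assert np.all(prof.q_mg_cm2 == 0.0)

    def test_schedule_mismatch(self):
        with pytest.raises(InvalidInputError, match="mismatch"):
            cumulative_release(np.zeros(5), make_experiment())

    @pytest.mark.parametrize("v_s", [1.0, 3.0, 10.0])
    def test_exactly_inverts_forward_withdrawal(self, v_s):
        """Independent forward simulation of sampling/replacement is inverted
        to 1e-9 by the mass-balance correction, for any aliquot volume."""
        q_true = 0.41 * np.sqrt(TIMES)
        V, A = 50.0, 3.8
        # oracle: explicit vessel bookkeeping
        mass_in_vessel = 0.0
        released_prev = 0.0
        conc = []
        for q in q_true:
            mass_in_vessel += (q - released_prev) * A
            released_prev = q
            c = mass_in_vessel / V
            conc.append(c)
            mass_in_vessel -= c * v_s
        exp = make_experiment(times=TIMES, sample_volume_ml=v_s)
        prof = cumulative_release(np.array(conc), exp)
        np.testing.assert_allclose(prof.q_mg_cm2, q_true, rtol=1e-9)

    def test_non_monotone_flagged(self):
        with pytest.warns(UserWarning, match="decreases"):
            cumulative_release(
                np.array([1.0, 0.2, 1.0, 1.1, 1.2, 1.3]), make_experiment()
            )


class TestKineticFits:
    def test_higuchi_noiseless(self):
        prof = ReleaseProfile(TIMES, 0.41 * np.sqrt(TIMES))
        fit = fit_release_model(prof, "higuchi")
        assert fit.params["kH"] == pytest.approx(0.41, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_order_beats_higuchi_on_linear_data(self):
        prof = ReleaseProfile(TIMES, 0.03 * TIMES)
        hig = fit_release_model(prof, "higuchi")
        ranking = compare_models(prof, q_inf=10.0)
        assert hig.r_squared < 1.0
        assert ranking.iloc[0]["model"] == "zero"

    def test_weibull_beta_one_is_first_order(self):
        k1 = 0.02
        q_inf = 5.0
        prof = ReleaseProfile(TIMES, q_inf * (1.0 - np.exp(-k1 * TIMES)))
        first = fit_release_model(prof, "first", q_inf=q_inf)
        weib = fit_release_model(prof, "weibull", q_inf=q_inf)
        assert first.params["k1"] == pytest.approx(k1, rel=1e-6)
        assert weib.params["beta"] == pytest.approx(1.0, rel=1e-4)
        assert 1.0 / weib.params["tau_d"] == pytest.approx(k1, rel=1e-4)

    def test_korsmeyer_peppas_recovery_and_window(self):
        kKP, n, q_inf = 0.05, 0.5, 10.0
        t = np.array([4.0, 9.0, 16.0, 36.0, 64.0, 100.0, 625.0])
        q = q_inf * kKP * t ** n
        fit = fit_release_model(ReleaseProfile(t, q), "korsmeyer_peppas",
                                q_inf=q_inf)
        assert fit.params["kKP"] == pytest.approx(kKP, rel=1e-9)
        assert fit.params["n"] == pytest.approx(n, rel=1e-9)
        # the 625-min point has Q/q_inf > 0.6 and must be excluded
        assert fit.n_points == t.size - 1

    def test_qinf_required(self):
        prof = ReleaseProfile(TIMES, 0.41 * np.sqrt(TIMES))
        with pytest.raises(InvalidInputError, match="q_inf"):
            fit_release_model(prof, "first")

    def test_empty_higuchi_window(self):
        prof = ReleaseProfile(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InsufficientDataError):
            fit_release_model(prof, "higuchi")

    def test_true_model_tops_ranking_noiseless(self):
        q_inf = 4.0
        prof = ReleaseProfile(TIMES, release_law("weibull",
                              {"q_inf": q_inf, "beta": 1.3, "tau_d": 70.0}, TIMES))
        ranking = compare_models(prof, q_inf=q_inf)
        assert ranking.iloc[0]["model"] == "weibull"

    def test_higuchi_survives_noise(self):
        rng = np.random.default_rng(5)
        q = 0.41 * np.sqrt(TIMES) + rng.normal(0, 0.05, TIMES.size)
        ranking = compare_models(ReleaseProfile(TIMES, np.clip(q, 0, None)),
                                 q_inf=15.0 / 3.8)
        r2 = ranking.set_index("model").loc["higuchi", "r_squared"]
        assert r2 > 0.9

    def test_three_point_profile_warns(self):
        t = np.array([15.0, 60.0, 150.0])
        prof = ReleaseProfile(t, 0.4 * np.sqrt(t))
        with pytest.warns(UserWarning, match="degrees of freedom"):
            fit_release_model(prof, "weibull", q_inf=10.0)


class TestRateComparison:
    def test_identical_groups(self):
        summary, tests = release_rate_comparison(
            {"A": [0.4, 0.4, 0.4], "B": [0.4, 0.4, 0.4]}
        )
        assert tests.iloc[0]["t"] == 0.0
        assert tests.iloc[0]["p"] == 1.0

    def test_single_replicate_descriptive_only(self):
        with pytest.warns(UserWarning, match="descriptive"):
            summary, tests = release_rate_comparison(
                {"A": [0.4], "B": [0.5, 0.52, 0.48]}
            )
        assert tests.empty
        assert np.isnan(summary.set_index("formulation_id").loc["A", "sd"])

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            release_rate_comparison({"A": [], "B": [0.4, 0.5]})

    def test_power_at_reference_effect_size(self):
        """Groups drawn at the two extreme reference rates (0.41 +/- 0.02 vs
        0.52 +/- 0.03, n = 6) separate at p < 0.05 in >= 95% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.41, 0.02, 6)
            b = rng.normal(0.52, 0.03, 6)
            _, tests = release_rate_comparison({"A": a, "B": b})
            hits += bool(tests.iloc[0]["p"] < 0.05)
        assert hits / n_seeds >= 0.95


class TestGeneratorPipeline:
    @pytest.mark.parametrize("fid", ["F-5", "F-6", "F-7"])
    def test_end_to_end_noiseless_recovery(self, fid, higuchi_rates, calibration):
        """Absorbance -> concentration -> correction -> refit returns the
        generating rate to 1e-6 for every studied formulation."""
        kH, _, dose = higuchi_rates[fid]
        exp, truth = gen_release_experiment(
            "higuchi", {"kH": kH}, loaded_dose_mg=dose, noise_a=0.0,
            cap_at_dose=False, seed=0,
        )
        conc = absorbance_to_conc(exp.absorbances[0], calibration)
        prof = cumulative_release(conc, exp)
        fit = fit_release_model(prof, "higuchi")
        assert fit.params["kH"] == pytest.approx(kH, abs=1e-6)
        np.testing.assert_allclose(prof.q_mg_cm2, truth.q_mg_cm2, rtol=1e-9)

    def test_mass_balance_with_cap(self):
        """With dose capping the released mass never exceeds the load."""
        with pytest.warns(UserWarning, match="capped"):
            exp, truth = gen_release_experiment(
                "higuchi", {"kH": 0.41}, loaded_dose_mg=15.0, noise_a=0.0,
                cap_at_dose=True,
            )
        assert np.all(truth.q_mg_cm2 * exp.orifice_area_cm2 <= 15.0 + 1e-9)
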