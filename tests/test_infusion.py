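import numpy as np
import pytest

import vancosim as vs
from vancosim.infusion import _conc_at, _disposition

from conftest import random_params, random_regimen


def single_dose(amount, tinf=1.0, horizon=96.0):
    return vs.DosingRegimen(
        loading_dose=amount, maintenance_dose=0.0, interval=12.0,
        infusion_duration=tinf, horizon=horizon,
    )


class TestClosedForm:
    def test_end_of_infusion_one_compartment(self, one_cpt_params):
        # (D / (Tinf * CL)) * (1 - exp(-k*Tinf)) with k = CL/V = 0.08 /h
        profile = vs.concentration_profile(one_cpt_params, single_dose(1000.0), [1.0])
        assert profile.conc[0] == pytest.approx(250.0 * -np.expm1(-0.08), rel=1e-12)

    def test_zero_doses_give_zero_profile(self, two_cpt_params):
        regimen = vs.DosingRegimen(loading_dose=0.0, maintenance_dose=0.0)
        profile = vs.concentration_profile(two_cpt_params, regimen, np.linspace(0, 48, 100))
        assert np.all(profile.conc == 0.0)

    def test_concentration_zero_before_first_dose(self, two_cpt_params, q12h_regimen):
        t = np.array([0.0, 0.5, 2.0])
        conc = vs.concentration_profile(two_cpt_params, q12h_regimen, t).conc
        assert conc[0] == 0.0 and conc[1] > 0.0

    def test_superposition_of_doses(self, two_cpt_params):
        # linear kinetics: the multi-dose profile is the sum of shifted
        # single-dose profiles, to machine precision
        regimen = vs.DosingRegimen(
            loading_dose=1500.0, maintenance_dose=750.0, interval=8.0,
            infusion_duration=1.5, horizon=60.0,
        )
        t = np.linspace(0.0, 60.0, 241)
        total = vs.concentration_profile(two_cpt_params, regimen, t).conc
        summed = np.zeros_like(total)
        for t0, amount in regimen.doses():
            one = vs.DosingRegimen(
                loading_dose=amount, maintenance_dose=0.0, interval=8.0,
                infusion_duration=1.5, start_time=t0, horizon=60.0,
            )
            summed += vs.concentration_profile(two_cpt_params, one, t).conc
        np.testing.assert_allclose(total, summed, rtol=1e-12, atol=1e-14)

    @pytest.mark.parametrize("bad_grid", [[], [2.0, 1.0], [1.0, 1.0]])
    def test_invalid_grids_rejected(self, two_cpt_params, q12h_regimen, bad_grid):
        with pytest.raises(ValueError):
            vs.concentration_profile(two_cpt_params, q12h_regimen, bad_grid)

    def test_regimen_invariants(self):
        with pytest.raises(ValueError):
            vs.DosingRegimen(infusion_duration=13.0, interval=12.0)
        with pytest.raises(ValueError):
            vs.DosingRegimen(interval=0.0)
        with pytest.raises(ValueError):
            vs.DosingRegimen(loading_dose=-1.0)


class TestOdeOracle:
    @pytest.mark.parametrize("two_compartment", [False, True])
    def test_closed_form_matches_ode(self, two_compartment):
        rng = np.random.default_rng(42)
        t = np.linspace(0.25, 72.0, 60)
        worst = 0.0
        for _ in range(20):
            params = random_params(rng, two_compartment)
            regimen = random_regimen(rng)
            closed = vs.concentration_profile(params, regimen, t).conc
            ode = vs.concentration_profile_ode(params, regimen, t).conc
            scale = np.maximum(np.abs(ode), 1e-9)
            worst = max(worst, float(np.max(np.abs(closed - ode) / scale)))
        assert worst < 1e-6

    def test_zero_dose_regimen(self, two_cpt_params):
        regimen = vs.DosingRegimen(loading_dose=0.0, maintenance_dose=0.0)
        ode = vs.concentration_profile_ode(two_cpt_params, regimen, np.linspace(0, 24, 25))
        assert np.all(ode.conc == 0.0)

    def test_mass_balance(self, two_cpt_params):
        # after the last infusion ends, everything administered must either
        # remain in the body or have been eliminated: dose = CL * AUC(0, inf)
        regimen = single_dose(1000.0, tinf=1.0, horizon=2000.0)
        t = np.linspace(1e-3, 2000.0, 20001)
        conc = vs.concentration_profile(two_cpt_params, regimen, t).conc
        auc = np.trapezoid(conc, t)
        assert two_cpt_params.cl * auc == pytest.approx(1000.0, rel=1e-3)


class TestTrough:
    def test_estimate_is_left_limit_before_fourth_dose(self, typical_patient, q12h_regimen):
        # doses at 0/12/24 h; the 36 h sample precedes the fourth dose, so
        # the dose starting at 36 h contributes nothing
        trough = vs.estimate_trough("llopis", typical_patient, q12h_regimen, 36.0)
        three_doses = vs.DosingRegimen(
            loading_dose=1000.0, maintenance_dose=1000.0, interval=12.0,
            infusion_duration=1.0, horizon=35.9,
        )
        params = vs.population_parameters("llopis", typical_patient)
        just_before = vs.concentration_profile(params, three_doses, [35.999999, 36.0]).conc[-1]
        assert trough == pytest.approx(just_before, rel=1e-9)
        assert trough > 0

    def test_steady_state_matches_closed_form(self, one_cpt_params):
        # after >=10 half-lives the simulated trough equals the analytic
        # steady-state trough of the 1-compartment infusion model
        cl, v = one_cpt_params.cl, one_cpt_params.vc
        k = cl / v
        tau, tinf, dose = 12.0, 1.0, 1000.0
        half_life = np.log(2) / k
        # the transient decays like exp(-k t): ~30 half-lives puts it
        # below the 1e-6 comparison tolerance
        n_doses = int(np.ceil(30 * half_life / tau)) + 1
        horizon = n_doses * tau
        regimen = vs.DosingRegimen(
            loading_dose=dose, maintenance_dose=dose, interval=tau,
            infusion_duration=tinf, horizon=horizon,
        )
        lam, coef = _disposition(cl, v)
        sim = float(_conc_at(lam, coef, v, regimen, n_doses * tau))
        ss = (
            (dose / (cl * tinf))
            * (1 - np.exp(-k * tinf))
            * np.exp(-k * (tau - tinf))
            / (1 - np.exp(-k * tau))
        )
        assert sim == pytest.approx(ss, rel=1e-6)

    def test_zero_dose_trough(self, typical_patient):
        regimen = vs.DosingRegimen(loading_dose=0.0, maintenance_dose=0.0)
        assert vs.estimate_trough("goti", typical_patient, regimen, 36.0) == 0.0

    def test_trough_beyond_horizon_rejected(self, typical_patient, q12h_regimen):
        with pytest.raises(ValueError, match="horizon"):
            vs.estimate_trough("goti", typical_patient, q12h_regimen, 72.0)

    def test_monotone_decreasing_in_clearance(self, q12h_regimen):
        troughs = []
        for cl in (2.0, 4.0, 6.0, 8.0):
            params = vs.PKParameters(cl=cl, vc=50.0, vp=80.0, q=7.0)
            lam, coef = _disposition(params.cl, params.vc, params.q, params.vp)
            troughs.append(float(_conc_at(lam, coef, params.vc, q12h_regimen, 36.0)))
        assert all(a > b for a, b in zip(troughs, troughs[1:]))

    def test_steady_state_trough_monotone_in_dose(self, one_cpt_params):
        def ss_trough(dose):
            regimen = vs.DosingRegimen(
                loading_dose=dose, maintenance_dose=dose, interval=12.0,
                infusion_duration=1.0, horizon=400.0,
            )
            lam, coef = _disposition(one_cpt_params.cl, one_cpt_params.vc)
            return float(_conc_at(lam, coef, one_cpt_params.vc, regimen, 396.0))

        values = [ss_trough(d) for d in (500.0, 1000.0, 1500.0)]
        assert values[0] < values[1] < values[2]


class TestPrediction:
    def test_zero_variability_degenerates_to_estimate(self, typical_patient, q12h_regimen):
        estimate = vs.estimate_trough("revilla", typical_patient, q12h_regimen)
        summary = vs.predict_trough(
            "revilla", typical_patient, q12h_regimen,
            vs.VariabilityOverride(0.0, 0.0), n_replicates=50, n_runs=3, seed=9,
        )
        assert summary.prediction == estimate
        assert summary.ci_low == summary.ci_high == estimate

    def test_fixed_seed_is_bit_identical(self, typical_patient, q12h_regimen):
        a = vs.predict_trough("goti", typical_patient, q12h_regimen, seed=77,
                              n_replicates=200, n_runs=5)
        b = vs.predict_trough("goti", typical_patient, q12h_regimen, seed=77,
                              n_replicates=200, n_runs=5)
        assert np.array_equal(a.replicate_troughs, b.replicate_troughs)
        assert a.run_medians == b.run_medians and a.prediction == b.prediction

    def test_summary_invariants(self, typical_patient, q12h_regimen):
        s = vs.predict_trough("llopis", typical_patient, q12h_regimen, seed=3,
                              n_replicates=400, n_runs=5)
        assert s.ci_low <= s.median <= s.ci_high
        assert s.replicate_troughs.size == 400
        assert len(s.run_medians) == 5
        assert np.all(s.replicate_troughs >= 0.0)

    def test_median_tracks_estimate_with_iiv_on_clearance_only(self, q12h_regimen):
        # the multiplicative log-normal effect has median 1, and the trough
        # is monotone in CL, so the replicate median tracks the estimate
        pop = vs.PKParameters(cl=4.0, vc=50.0, vp=80.0, q=7.0)
        lam, coef = _disposition(pop.cl, pop.vc, pop.q, pop.vp)
        estimate = float(_conc_at(lam, coef, pop.vc, q12h_regimen, 36.0))
        rng = np.random.default_rng(21)
        cl = pop.cl * np.exp(rng.normal(0.0, 0.3, size=4000))
        lam, coef = _disposition(cl, np.full_like(cl, pop.vc),
                                 np.full_like(cl, pop.q), np.full_like(cl, pop.vp))
        troughs = _conc_at(lam, coef, np.full_like(cl, pop.vc), q12h_regimen, 36.0)
        median = np.median(troughs)
        boot = np.random.default_rng(22)
        boot_medians = [
            np.median(boot.choice(troughs, troughs.size, replace=True)) for _ in range(200)
        ]
        se = np.std(boot_medians)
        assert abs(median - estimate) < 3 * se + 1e-9

    def test_replicate_guard(self, typical_patient, q12h_regimen):
        with pytest.raises(ValueError):
            vs.predict_trough("goti", typical_patient, q12h_regimen, n_replicates=1, seed=0)


class TestAuc24:
    @pytest.mark.parametrize(
        "cl, daily_dose, auc, label",
        [
            (4.0, 2000.0, 500.0, "in_target"),
            (2.5, 2000.0, 800.0, "toxicity_risk"),
            (4.0, 0.0, 0.0, "below"),
            (4.0, 2400.0, 600.0, "in_target"),
            (4.0, 2600.0, 650.0, "above_target"),
            (4.0, 2800.0, 700.0, "toxicity_risk"),
        ],
    )
    def test_auc_and_classification(self, cl, daily_dose, auc, label):
        value, cls = vs.steady_state_auc24(cl, daily_dose)
        assert value == pytest.approx(auc)
        assert cls == label

    def test_nonpositive_clearance_rejected(self):
        with pytest.raises(ValueError):
            vs.steady_state_auc24(0.0, 2000.0)

    def test_regimen_daily_dose(self, q12h_regimen):
        assert q12h_regimen.daily_dose == 2000.0
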