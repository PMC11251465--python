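"""Trial engine: resampling, regimen effects, test calibration, sample size."""

import numpy as np
import pytest

from ea_trial_sim.pkpd import PDParams, PKParams
from ea_trial_sim.records import Covariates, PatientRecord
from ea_trial_sim.trial_engine import (
    Regimen,
    TrialDesign,
    apply_regimen,
    arm_probability_table,
    estimate_power,
    find_sample_size,
    sample_virtual_patient,
    simulate_trial,
    standard_arms,
    sweep_ed50,
    two_proportion_n,
    welch_ttest_binary,
)

LEV = "levetiracetam"


def make_patient(b0=0.5, lam=0.0, ed50=8.0, doses=()):
    cov = Covariates(
        age=60, sex="F", hunt_hess=3, fisher=3, time_to_eeg=24, eeg_duration=120, weight=75
    )
    pkpd = {
        LEV: (PKParams(k_e=0.1, V=0.6), PDParams(ed50=ed50, hill=2.0, b0=b0, lam=lam))
    }
    return PatientRecord(
        patient_id="X0", covariates=cov, pkpd=pkpd, doses=tuple(doses), mrs=2
    )


def null_design(n_per_arm=100, alpha=0.05):
    placebo = Regimen(LEV, "placebo")
    return TrialDesign(arms=(placebo, placebo), n_per_arm=n_per_arm, alpha=alpha, contrast=(0, 1))


class TestSampleVirtualPatient:
    def test_single_patient_cohort(self):
        p = make_patient()
        rng = np.random.default_rng(0)
        assert all(sample_virtual_patient([p], rng) is p for _ in range(5))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_virtual_patient([], np.random.default_rng(0))

    def test_bootstrap_covariate_means(self, cohort48):
        ages = np.array([r.covariates.age for r in cohort48.records])
        rng = np.random.default_rng(1)
        draws = np.array(
            [sample_virtual_patient(cohort48.records, rng).covariates.age for _ in range(10000)]
        )
        mc_se = ages.std() / np.sqrt(10000)
        assert abs(draws.mean() - ages.mean()) < 3 * mc_se

    def test_seeded_draws_reproducible(self, cohort48):
        ids_a = [
            sample_virtual_patient(cohort48.records, np.random.default_rng(9)).patient_id
            for _ in range(1)
        ]
        ids_b = [
            sample_virtual_patient(cohort48.records, np.random.default_rng(9)).patient_id
            for _ in range(1)
        ]
        assert ids_a == ids_b


class TestApplyRegimen:
    def test_placebo_untreated_constant_baseline_gives_emax_b0(self):
        patient = make_patient(b0=0.5, lam=0.0)
        exposure, burden = apply_regimen(patient, Regimen(LEV, "placebo"))
        assert exposure.e_max == pytest.approx(0.5)
        assert exposure.mean_conc == 0.0
        np.testing.assert_allclose(burden.values, 0.5)

    def test_emax_non_increasing_in_bolus_dose(self, cohort48):
        arms = [Regimen(LEV, "bolus_q", d) for d in (15.0, 7.0, 3.0)]
        for patient in cohort48.records[:12]:
            e = [apply_regimen(patient, arm)[0].e_max for arm in arms]
            placebo = apply_regimen(patient, Regimen(LEV, "placebo"))[0].e_max
            assert e[0] <= e[1] + 1e-12 <= e[2] + 2e-12 <= placebo + 3e-12

    def test_doubling_dose_never_increases_emax(self, cohort48):
        for patient in cohort48.records[:12]:
            lo = apply_regimen(patient, Regimen(LEV, "bolus_q", 5.0))[0].e_max
            hi = apply_regimen(patient, Regimen(LEV, "bolus_q", 10.0))[0].e_max
            assert hi <= lo + 1e-12

    def test_missing_pkpd_params_rejected(self):
        patient = make_patient()
        with pytest.raises(ValueError, match="lacks PK/PD parameters"):
            apply_regimen(patient, Regimen("propofol", "infusion", 0.5))


class TestSimulateTrial:
    def test_maximal_separation_rejects(self):
        table = np.array([[0.0, 1.0]])
        design = null_design(n_per_arm=5)
        result = simulate_trial([make_patient()], None, design, 3, prob_table=table)
        assert result.p_value < design.alpha
        assert result.proportions == (0.0, 1.0)

    def test_fixed_seed_reproducible(self, cohort48, outcome_model48):
        design = TrialDesign(arms=tuple(standard_arms(LEV)), n_per_arm=20, contrast=(1, 3))
        a = simulate_trial(cohort48.records, outcome_model48, design, 77)
        b = simulate_trial(cohort48.records, outcome_model48, design, 77)
        assert a == b

    def test_tiny_arm_rejected(self):
        with pytest.raises(ValueError):
            null_design(n_per_arm=1)

    def test_welch_degenerate_arms(self):
        t, p = welch_ttest_binary(np.zeros(10), np.zeros(10))
        assert p == 1.0
        t, p = welch_ttest_binary(np.zeros(10), np.ones(10))
        assert p == 0.0


class TestEstimatePower:
    def test_null_size_matches_level(self):
        table = np.array([[0.4, 0.4]])
        est = estimate_power(
            [], None, null_design(200), replicates=2000, rng_seed=5, prob_table=table
        )
        band = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(est.power - 0.05) <= band

    def test_power_monotone_in_n(self):
        table = np.array([[0.60, 0.45]])
        design = null_design(50)
        lo = estimate_power(
            [], None, design, n_per_arm=50, replicates=2000, rng_seed=6, prob_table=table
        )
        hi = estimate_power(
            [], None, design, n_per_arm=200, replicates=2000, rng_seed=7, prob_table=table
        )
        joint_se = np.hypot(lo.se, hi.se)
        assert hi.power >= lo.power - 3 * joint_se

    def test_replicate_count_convergence(self):
        table = np.array([[0.60, 0.50]])
        design = null_design(100)
        a = estimate_power(
            [], None, design, replicates=500, rng_seed=8, prob_table=table
        )
        b = estimate_power(
            [], None, design, replicates=5000, rng_seed=9, prob_table=table
        )
        assert abs(a.power - b.power) <= 3 * np.hypot(a.se, b.se)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            estimate_power([], None, null_design(), replicates=50, prob_table=np.array([[0.5, 0.5]]))


class TestFindSampleSize:
    def test_zero_effect_never_reaches_target(self):
        table = np.array([[0.5, 0.5]])
        res = find_sample_size(
            [], None, null_design(), n_max=400, replicates=500, rng_seed=10, prob_table=table
        )
        assert not res.reached
        assert res.n_per_arm is None
        assert res.power_at_n < 0.2

    def test_deterministic_under_seed(self):
        table = np.array([[0.6, 0.4]])
        kwargs = dict(n_max=1000, replicates=500, rng_seed=11, prob_table=table)
        a = find_sample_size([], None, null_design(), **kwargs)
        b = find_sample_size([], None, null_design(), **kwargs)
        assert a == b


class TestTwoProportionN:
    def test_symmetric_in_arguments(self):
        assert two_proportion_n(0.6, 0.45) == two_proportion_n(0.45, 0.6)

    def test_diverges_as_effect_vanishes(self):
        assert two_proportion_n(0.5, 0.50001) > 1e8

    @pytest.mark.parametrize("bad", [(0.5, 0.5), (0.0, 0.5), (0.5, 1.0)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            two_proportion_n(*bad)


class TestSweepEd50:
    def test_huge_ed50_multiplier_gives_null_power(self, cohort48, outcome_model48):
        """An ineffective drug makes the contrasted arms identical in law."""
        design = TrialDesign(arms=tuple(standard_arms(LEV)), n_per_arm=100, contrast=(1, 3))
        sweep = sweep_ed50(
            cohort48.records,
            outcome_model48,
            design,
            multipliers=[1e6],
            replicates=1000,
            rng_seed=12,
        )
        assert abs(sweep.power[0] - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 1000) + 0.01

    def test_power_non_increasing_in_multiplier(self, cohort48, outcome_model48):
        design = TrialDesign(arms=tuple(standard_arms(LEV)), n_per_arm=150, contrast=(1, 3))
        sweep = sweep_ed50(
            cohort48.records,
            outcome_model48,
            design,
            multipliers=[0.05, 1.0, 1e4],
            replicates=1000,
            rng_seed=13,
        )
        ses = np.array(sweep.se)
        powers = np.array(sweep.power)
        for k in range(2):
            assert powers[k + 1] <= powers[k] + 3 * np.hypot(ses[k], ses[k + 1])

    def test_invalid_multiplier_rejected(self, cohort48, outcome_model48):
        design = TrialDesign(arms=tuple(standard_arms(LEV)), n_per_arm=50, contrast=(1, 3))
        with pytest.raises(ValueError):
            sweep_ed50(cohort48.records, outcome_model48, design, multipliers=[-1.0])
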