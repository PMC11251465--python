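"""One-compartment PK, Hill PD, stochastic observation and parameter fitting."""

import numpy as np
import pytest
from pk_oracle import ode_concentration, random_schedule

from ea_trial_sim.ea_burden import BurdenSeries, compute_burden
from ea_trial_sim.pkpd import (
    ConcentrationProfile,
    DoseEvent,
    PDParams,
    PKParams,
    concentration_profile,
    fit_pkpd,
    hill_suppression,
    rescale_ed50,
    sample_burden_fractions,
    sample_labels,
    simulate_burden,
    simulate_burden_multidrug,
    time_grid,
)

LEV = "levetiracetam"


class TestConcentrationProfile:
    def test_bolus_initial_and_half_life(self):
        pk = PKParams(k_e=np.log(2) / 7.0, V=0.5)
        t = np.array([0.0, 7.0, 14.0])
        prof = concentration_profile([DoseEvent(LEV, 0.0, "bolus", 7.0)], pk, t)
        np.testing.assert_allclose(prof.values, [14.0, 7.0, 3.5])

    def test_infusion_steady_state(self):
        pk = PKParams(k_e=0.2, V=2.0)
        t = time_grid(200)
        prof = concentration_profile(
            [DoseEvent(LEV, 0.0, "infusion_start", 1.0)], pk, t
        )
        assert prof.values[-1] == pytest.approx(1.0 / (0.2 * 2.0), rel=1e-6)

    def test_zero_before_first_dose(self):
        pk = PKParams(k_e=0.1, V=1.0)
        t = time_grid(24)
        prof = concentration_profile([DoseEvent(LEV, 12.0, "bolus", 5.0)], pk, t)
        assert np.all(prof.values[t < 12.0] == 0.0)

    def test_superposition_linearity(self):
        rng = np.random.default_rng(5)
        pk = PKParams(k_e=0.3, V=1.5)
        t = time_grid(72)
        a = random_schedule(rng)
        # keep boluses only so merged infusion intervals still alternate
        b = [ev for ev in random_schedule(rng) if ev.route == "bolus"]
        c_a = concentration_profile(a, pk, t).values
        c_b = concentration_profile(b, pk, t).values
        c_ab = concentration_profile(a + b, pk, t).values
        np.testing.assert_allclose(c_ab, c_a + c_b, rtol=1e-12, atol=1e-12)

    def test_matches_numeric_ode_oracle(self):
        rng = np.random.default_rng(17)
        t = time_grid(72)
        for _ in range(10):
            k_e = float(rng.uniform(0.05, 1.0))
            V = float(rng.uniform(0.3, 5.0))
            doses = random_schedule(rng)
            closed = concentration_profile(doses, PKParams(k_e=k_e, V=V), t).values
            numeric = ode_concentration(doses, k_e, V, t)
            scale = max(closed.max(), 1e-9)
            assert np.max(np.abs(closed - numeric)) / scale < 1e-3

    def test_unmatched_infusion_stop_rejected(self):
        pk = PKParams(k_e=0.1, V=1.0)
        with pytest.raises(ValueError, match="infusion_stop"):
            concentration_profile(
                [DoseEvent(LEV, 5.0, "infusion_stop")], pk, time_grid(10)
            )

    def test_nonpositive_pk_params_rejected(self):
        with pytest.raises(ValueError):
            PKParams(k_e=0.0, V=1.0)
        with pytest.raises(ValueError):
            PKParams(k_e=0.1, V=-1.0)


class TestHillSuppression:
    @pytest.mark.parametrize(
        "c, hill, expected",
        [(5.0, 2.0, 0.5), (0.0, 2.0, 0.0), (15.0, 1.0, 0.75)],
    )
    def test_known_points(self, c, hill, expected):
        pd = PDParams(ed50=5.0, hill=hill, b0=0.5, lam=0.0)
        assert hill_suppression(c, pd) == pytest.approx(expected)

    def test_monotone_and_saturating(self):
        pd = PDParams(ed50=3.0, hill=2.5, b0=0.5, lam=0.0)
        c = np.linspace(0, 500, 2000)
        s = hill_suppression(c, pd)
        assert np.all(np.diff(s) >= 0)
        assert s[-1] > 0.999
        assert hill_suppression(pd.ed50, pd) == pytest.approx(0.5, abs=1e-12)

    def test_negative_concentration_rejected(self):
        pd = PDParams(ed50=3.0, hill=1.0, b0=0.5, lam=0.0)
        with pytest.raises(ValueError):
            hill_suppression(-1.0, pd)


class TestSimulateBurden:
    def test_no_drug_constant_baseline(self):
        pd = PDParams(ed50=5.0, hill=1.0, b0=0.7, lam=0.0)
        t = time_grid(48)
        conc = ConcentrationProfile(times=t, values=np.zeros_like(t))
        np.testing.assert_allclose(simulate_burden(pd, conc).values, 0.7)

    def test_constant_ed50_concentration_halves_burden(self):
        pd = PDParams(ed50=5.0, hill=2.0, b0=0.8, lam=0.0)
        t = time_grid(48)
        conc = ConcentrationProfile(times=t, values=np.full_like(t, 5.0))
        np.testing.assert_allclose(simulate_burden(pd, conc).values, 0.4)

    def test_baseline_decay_closed_form(self):
        pd = PDParams(ed50=5.0, hill=1.0, b0=0.8, lam=0.01)
        t = time_grid(100.5)
        conc = ConcentrationProfile(times=t, values=np.zeros_like(t))
        out = simulate_burden(pd, conc)
        assert out.values[600] == pytest.approx(0.8 * np.exp(-1.0))  # t = 100 h

    def test_higher_concentration_never_raises_burden(self):
        rng = np.random.default_rng(3)
        pd = PDParams(ed50=4.0, hill=2.0, b0=0.6, lam=0.002)
        t = time_grid(24)
        base = rng.uniform(0, 10, size=t.size)
        lo = ConcentrationProfile(times=t, values=base)
        hi = ConcentrationProfile(times=t, values=base + rng.uniform(0, 5, size=t.size))
        assert np.all(
            simulate_burden(pd, hi).values <= simulate_burden(pd, lo).values + 1e-12
        )

    def test_multidrug_composition_multiplies_suppressions(self):
        t = time_grid(12)
        pd_a = PDParams(ed50=5.0, hill=1.0, b0=0.8, lam=0.0)
        pd_b = PDParams(ed50=1.0, hill=1.0, b0=0.8, lam=0.0)
        conc_a = ConcentrationProfile(times=t, values=np.full_like(t, 5.0))
        conc_b = ConcentrationProfile(times=t, values=np.full_like(t, 1.0))
        out = simulate_burden_multidrug(pd_a, [(pd_a, conc_a), (pd_b, conc_b)], t)
        np.testing.assert_allclose(out.values, 0.8 * 0.5 * 0.5)


class TestSampleLabels:
    def test_degenerate_windows(self):
        series = BurdenSeries(times=np.array([0.0, 1 / 6]), values=np.array([0.0, 1.0]))
        labels = sample_labels(series, 1)
        assert labels.labels[:300].sum() == 0
        assert labels.labels[300:].sum() == 300

    def test_observed_fraction_within_binomial_band(self):
        series = BurdenSeries(times=np.array([0.0]), values=np.array([0.5]))
        hits = 0
        for seed in range(200):
            frac = compute_burden(sample_labels(series, seed)).values[0]
            hits += abs(frac - 0.5) <= 0.09  # 3 sigma of Binomial(300, .5)/300
        assert hits >= 195

    def test_seeded_reproducibility(self):
        series = BurdenSeries(times=np.arange(6) / 6, values=np.full(6, 0.3))
        a = sample_labels(series, 42).labels
        b = sample_labels(series, 42).labels
        np.testing.assert_array_equal(a, b)

    def test_fraction_shortcut_matches_label_distribution(self):
        # Binomial(300, b)/300 is the law of aggregating 300 Bernoulli labels
        series = BurdenSeries(times=np.arange(2000) / 6, values=np.full(2000, 0.3))
        via_labels = compute_burden(sample_labels(series, 0)).values
        direct = sample_burden_fractions(series, 1).values
        assert abs(via_labels.mean() - direct.mean()) < 0.005
        assert abs(via_labels.std() - direct.std()) < 0.005


class TestFitPkpd:
    def make_treated(self, seed=0, duration=240):
        true_pk = PKParams(k_e=0.08, V=0.6)
        true_pd = PDParams(ed50=8.0, hill=2.2, b0=0.6, lam=0.006)
        t = time_grid(duration)
        doses = [DoseEvent(LEV, float(h), "bolus", 7.0) for h in np.arange(2, duration, 8)]
        conc = concentration_profile(doses, true_pk, t)
        return true_pk, true_pd, doses, simulate_burden(true_pd, conc)

    def test_noise_free_self_consistency(self):
        true_pk, true_pd, doses, latent = self.make_treated()
        fit = fit_pkpd(latent, doses, LEV, rng_seed=3)
        assert fit.mse < 1e-10
        assert fit.pd_identifiable
        for true, est in [
            (true_pk.k_e, fit.pk.k_e),
            (true_pd.ed50, fit.pd.ed50),
            (true_pd.hill, fit.pd.hill),
            (true_pd.b0, fit.pd.b0),
        ]:
            assert abs(est - true) / true < 0.01

    def test_returned_mse_equals_recomputed_objective(self):
        _, _, doses, latent = self.make_treated()
        obs = sample_burden_fractions(latent, 4)
        fit = fit_pkpd(obs, doses, LEV, n_starts=2, max_evals=400, rng_seed=4)
        conc = concentration_profile(doses, fit.pk, obs.times)
        sim = simulate_burden(fit.pd, conc).values
        assert fit.mse == pytest.approx(np.mean((sim - obs.values) ** 2), rel=1e-9)

    def test_untreated_constant_burden(self):
        t = time_grid(48)
        obs = BurdenSeries(times=t, values=np.full_like(t, 0.4))
        fit = fit_pkpd(obs, [], LEV, rng_seed=0)
        assert not fit.pd_identifiable
        assert fit.pd.b0 == pytest.approx(0.4, abs=0.01)
        assert fit.pd.lam == pytest.approx(0.0, abs=1e-4)

    def test_short_record_rejected(self):
        t = time_grid(3)
        obs = BurdenSeries(times=t, values=np.full_like(t, 0.4))
        with pytest.raises(ValueError, match="36 burden bins"):
            fit_pkpd(obs, [], LEV)


def test_rescale_ed50_validates_and_scales():
    pd = PDParams(ed50=4.0, hill=1.0, b0=0.5, lam=0.0)
    assert rescale_ed50(pd, 2.5).ed50 == pytest.approx(10.0)
    with pytest.raises(ValueError):
        rescale_ed50(pd, 0.0)
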