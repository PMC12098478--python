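import math

import numpy as np
import pytest
from scipy import stats

from oncotraj import (
    Cohort,
    PatientRecord,
    StudyDesign,
    get_model,
    simulate_cohort,
)
from oncotraj.likelihood import (
    CohortLikelihood,
    cohort_negloglik,
    death_interval_density,
    mc_survival_oracle,
    metastasis_increment_loglik,
    patient_loglik,
    size_observation_loglik,
    survival_interval_prob,
)


class TestSizeObservation:
    def test_mode_value(self):
        s, sigma = 2.0, 0.1
        got = size_observation_loglik(s, s, sigma)
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi * (sigma * s) ** 2))

    def test_closed_form_value(self):
        got = size_observation_loglik(1.0, 1.1, 0.1)
        expected = stats.norm.logpdf(1.1, loc=1.0, scale=0.1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.8836, abs=2e-4)

    def test_symmetry(self):
        assert size_observation_loglik(2.0, 2.3, 0.2) == pytest.approx(
            size_observation_loglik(2.0, 1.7, 0.2)
        )

    def test_missing_contributes_zero(self):
        assert size_observation_loglik(1.0, np.nan, 0.1) == 0.0

    def test_lognormal_matches_scipy(self):
        got = size_observation_loglik(2.0, 2.5, 0.3, noise_kind="lognormal")
        expected = stats.lognorm.logpdf(2.5, s=0.3, scale=2.0)
        assert got == pytest.approx(expected, rel=1e-12)


class TestMetastasisIncrement:
    @pytest.mark.parametrize(
        "lam, dn, expected",
        [
            (1.0, 0, -1.0),
            (2.0, 3, math.log(8 / 6) - 2.0),
            (0.0, 0, 0.0),
        ],
    )
    def test_poisson_pmf_values(self, lam, dn, expected):
        assert metastasis_increment_loglik(lam, dn) == pytest.approx(expected)

    def test_impossible_event_sentinel(self):
        assert metastasis_increment_loglik(0.0, 1) == -math.inf

    def test_decreasing_counts_rejected(self):
        with pytest.raises(ValueError, match="-1"):
            metastasis_increment_loglik(1.0, -1)


class TestSurvivalIntervalProb:
    def test_m0_reduces_to_integrated_hazard(self, m1, oracle_theta):
        got = survival_interval_prob(m1, oracle_theta, 0.0, 2.0, 3, 0)
        from oncotraj.intensities import DeathSpec, cumulative_death_intensity

        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        lam = cumulative_death_intensity(
            DeathSpec(params["d_size"], params["d_metas"]), growth, [(0.0, 2.0, 3)]
        )
        assert got == pytest.approx(math.exp(-lam), rel=1e-12)

    def test_no_metastasis_feedback_is_m_independent(self, m1):
        theta = {"beta": 0.5, "m_basal": 0.05, "m_size": 0.1, "d_size": 0.02, "d_metas": 0.0}
        vals = [survival_interval_prob(m1, theta, 0.0, 2.0, 0, m) for m in range(4)]
        assert np.allclose(vals, vals[0], rtol=1e-12)

    def test_constant_hazard_for_every_m(self):
        model = get_model("m1")
        model.fixed = dict(model.fixed, S0=1.0)
        theta = {"beta": 1e-14, "m_basal": 0.7, "m_size": 0.0, "d_size": 0.3, "d_metas": 0.0}
        for m in range(4):
            got = survival_interval_prob(model, theta, 1.0, 3.0, 0, m)
            assert got == pytest.approx(math.exp(-0.3 * 2.0), rel=1e-10)

    def test_monotone_in_hazard_and_interval_length(self, m1, oracle_theta):
        base = survival_interval_prob(m1, oracle_theta, 0.0, 2.0, 1, 2)
        assert 0 < base <= 1
        harder = dict(oracle_theta, d_size=0.02)
        assert survival_interval_prob(m1, harder, 0.0, 2.0, 1, 2) < base
        harder = dict(oracle_theta, d_metas=0.4)
        assert survival_interval_prob(m1, harder, 0.0, 2.0, 1, 2) < base
        assert survival_interval_prob(m1, oracle_theta, 0.0, 3.0, 1, 2) < base

    @pytest.mark.parametrize("m", range(6))
    def test_reduction_vs_cubature_vs_mc(self, m1, oracle_theta, m):
        """The analytic reduction, the nested simplex cubature and the
        Monte-Carlo conditional-jump-time oracle agree (generic M1 case)."""
        red = survival_interval_prob(m1, oracle_theta, 0.0, 2.0, 0, m)
        cub = survival_interval_prob(
            m1, oracle_theta, 0.0, 2.0, 0, m, method="cubature", rel_tol=1e-7
        )
        assert red == pytest.approx(cub, rel=1e-6)
        est, se = mc_survival_oracle(
            m1, oracle_theta, 0.0, 2.0, 0, m, n_samples=300_000, seed=m
        )
        if se == 0:
            assert est == pytest.approx(red, rel=1e-9)
        else:
            assert abs(red - est) < 4 * se

    def test_m2_reduction_vs_cubature(self, m2):
        theta = {"beta": 0.5, "m_division": 0.05, "d_size": 0.01, "d_metas": 0.2}
        for m in (0, 1, 3):
            red = survival_interval_prob(m2, theta, 1.0, 3.0, 0, m)
            cub = survival_interval_prob(
                m2, theta, 1.0, 3.0, 0, m, method="cubature", rel_tol=1e-7
            )
            assert red == pytest.approx(cub, rel=1e-6)

    def test_gompertz_quadrature_vs_cubature(self):
        m3 = get_model("m3")
        theta = dict(m3.true_theta, m_basal=0.05, m_size=0.01, d_metas=0.1)
        for m in (0, 1, 2):
            red = survival_interval_prob(m3, theta, 5.0, 7.0, 1, m)
            cub = survival_interval_prob(
                m3, theta, 5.0, 7.0, 1, m, method="cubature", rel_tol=1e-7
            )
            assert red == pytest.approx(cub, rel=1e-6)

    def test_invalid_arguments(self, m1, oracle_theta):
        with pytest.raises(ValueError):
            survival_interval_prob(m1, oracle_theta, 0.0, 2.0, 0, -1)
        with pytest.raises(ValueError):
            survival_interval_prob(m1, oracle_theta, 2.0, 2.0, 0, 0)


class TestDeathIntervalDensity:
    def test_constant_hazard_exponential_density(self):
        model = get_model("m1")
        model.fixed = dict(model.fixed, S0=1.0)
        theta = {"beta": 1e-14, "m_basal": 0.7, "m_size": 0.0, "d_size": 0.3, "d_metas": 0.0}
        got = death_interval_density(model, theta, 0.0, 2.0, 0, 1)
        assert got == pytest.approx(0.3 * math.exp(-0.6), rel=1e-10)

    def test_zero_hazard_gives_zero_density(self, m1):
        theta = {"beta": 0.5, "m_basal": 0.05, "m_size": 0.1, "d_size": 0.0, "d_metas": 0.0}
        assert death_interval_density(m1, theta, 0.0, 2.0, 0, 1) == 0.0

    def test_factorises_into_hazard_times_survival(self, m1, oracle_theta):
        from oncotraj.intensities import death_intensity

        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        death = m1.build_death(params)
        lam_d = float(death_intensity(death, growth, 2.0, 2))
        got = death_interval_density(m1, oracle_theta, 0.0, 2.0, 0, 2)
        surv = survival_interval_prob(m1, oracle_theta, 0.0, 2.0, 0, 2)
        assert got == pytest.approx(lam_d * surv, rel=1e-12)


class TestSubDistribution:
    def test_increment_times_survival_is_subdistribution(self, m1, oracle_theta):
        """sum_m P(m jumps) * P(survive | m) + death terms stays <= 1 and
        the survival part alone equals the Poisson-marginal survival."""
        from oncotraj.intensities import cumulative_metastasis_intensity

        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        met = m1.build_metastasis(params)
        lam = cumulative_metastasis_intensity(met, growth, 0.0, 1.0)
        total = 0.0
        for m in range(40):
            p_m = math.exp(metastasis_increment_loglik(lam, m))
            total += p_m * survival_interval_prob(m1, oracle_theta, 0.0, 1.0, 0, m)
        assert total <= 1.0 + 1e-12
        # Campbell-formula closed form for the Poisson-marginal survival
        from oncotraj.likelihood import _weighted_metastasis_integral
        from oncotraj.intensities import sqrt_volume_integral

        jlam = _weighted_metastasis_integral(met, growth, 0.0, 1.0, 1.0, params["d_metas"])
        marginal = math.exp(
            -params["d_size"] * sqrt_volume_integral(growth, 0.0, 1.0) - (lam - jlam)
        )
        assert total == pytest.approx(marginal, rel=1e-10)

    def test_simulator_matches_interval_probabilities(self, m1, oracle_theta):
        """Empirical frequency of (m new metastases, survive) events over
        [0, T] matches Poisson(m) x Eq-14 survival."""
        from oncotraj.simulate import simulate_patient
        from oncotraj.intensities import cumulative_metastasis_intensity

        T = 2.0
        design = StudyDesign(t_max=T)
        n = 4000
        rngs = np.random.SeedSequence(13).spawn(n)
        events = np.zeros((n, 2))
        for i, s in enumerate(rngs):
            traj = simulate_patient(m1, oracle_theta, design, np.random.default_rng(s))
            events[i] = (traj.metastasis_times.size, traj.death_time is None)
        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        met = m1.build_metastasis(params)
        lam = cumulative_metastasis_intensity(met, growth, 0.0, T)
        for m in range(3):
            p_theory = math.exp(
                metastasis_increment_loglik(lam, m)
            ) * survival_interval_prob(m1, oracle_theta, 0.0, T, 0, m)
            # survivors at T retain all m jumps; the dead are truncated, so
            # count (m, survived) outcomes only
            p_emp = np.mean((events[:, 0] == m) & (events[:, 1] == 1))
            se = math.sqrt(p_theory * (1 - p_theory) / n)
            assert abs(p_emp - p_theory) < 4 * se + 1e-12


class TestPatientLoglik:
    def _record(self, times, sizes, counts, death):
        return PatientRecord(
            patient_id="p0",
            times=np.asarray(times, dtype=float),
            size_obs=np.asarray(sizes, dtype=float),
            n_metastases=np.asarray(counts, dtype=float),
            death=np.asarray(death, dtype=int),
        )

    def test_single_interval_composition(self, m1, oracle_theta):
        """One survived interval = size term + Poisson term + ln survival."""
        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        s1 = float(growth.volume(1.0))
        rec = self._record([0.0, 1.0], [0.06, s1 * 1.05], [0, 2], [0, 0])
        got = patient_loglik(m1, oracle_theta, rec)
        from oncotraj.intensities import cumulative_metastasis_intensity

        met = m1.build_metastasis(params)
        lam = cumulative_metastasis_intensity(met, growth, 0.0, 1.0)
        expected = (
            float(size_observation_loglik(params["S0"], 0.06, params["sigma_S"]))
            + float(size_observation_loglik(s1, s1 * 1.05, params["sigma_S"]))
            + float(metastasis_increment_loglik(lam, 2))
            + math.log(survival_interval_prob(m1, oracle_theta, 0.0, 1.0, 0, 2))
        )
        assert got.loglik == pytest.approx(expected, rel=1e-10)

    def test_death_interval_uses_density(self, m1, oracle_theta):
        rec = self._record([0.0, 1.0, 1.7], [0.066, 0.08, np.nan], [0, 1, 2], [0, 0, 1])
        got = patient_loglik(m1, oracle_theta, rec)
        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        from oncotraj.intensities import cumulative_metastasis_intensity

        met = m1.build_metastasis(params)
        expected = (
            float(size_observation_loglik(params["S0"], 0.066, params["sigma_S"]))
            + float(size_observation_loglik(float(growth.volume(1.0)), 0.08, params["sigma_S"]))
            + float(metastasis_increment_loglik(
                cumulative_metastasis_intensity(met, growth, 0.0, 1.0), 1))
            + math.log(survival_interval_prob(m1, oracle_theta, 0.0, 1.0, 0, 1))
            + float(metastasis_increment_loglik(
                cumulative_metastasis_intensity(met, growth, 1.0, 1.7), 1))
            + math.log(death_interval_density(m1, oracle_theta, 1.0, 1.7, 1, 1))
        )
        assert got.loglik == pytest.approx(expected, rel=1e-10)

    def test_chapman_kolmogorov_skip(self, m1, oracle_theta):
        """Masking an interior count (patient survives) equals deleting the
        visit entirely when its size is also missing."""
        full = self._record(
            [0.0, 1.0, 2.0, 3.0], [0.066, 0.08, 0.12, 0.18], [0, 1, 1, 2], [0, 0, 0, 0]
        )
        masked = self._record(
            [0.0, 1.0, 2.0, 3.0],
            [0.066, 0.08, np.nan, 0.18],
            [0, 1, np.nan, 2],
            [0, 0, 0, 0],
        )
        deleted = self._record([0.0, 1.0, 3.0], [0.066, 0.08, 0.18], [0, 1, 2], [0, 0, 0])
        ll_masked = patient_loglik(m1, oracle_theta, masked).loglik
        ll_deleted = patient_loglik(m1, oracle_theta, deleted).loglik
        assert ll_masked == pytest.approx(ll_deleted, rel=1e-10)
        assert ll_masked != pytest.approx(patient_loglik(m1, oracle_theta, full).loglik)

    def test_skip_equals_explicit_sum_over_intermediates(self, m1, oracle_theta):
        """The merged interval equals the Chapman-Kolmogorov sum over the
        unobserved intermediate count."""
        masked = self._record(
            [0.0, 1.0, 2.0], [0.066, np.nan, 0.12], [0, np.nan, 2], [0, 0, 0]
        )
        ll = patient_loglik(m1, oracle_theta, masked).loglik
        total = 0.0
        from oncotraj.intensities import cumulative_metastasis_intensity

        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        met = m1.build_metastasis(params)
        for n_mid in range(0, 3):
            t1 = math.exp(
                metastasis_increment_loglik(
                    cumulative_metastasis_intensity(met, growth, 0.0, 1.0), n_mid
                )
            ) * survival_interval_prob(m1, oracle_theta, 0.0, 1.0, 0, n_mid)
            t2 = math.exp(
                metastasis_increment_loglik(
                    cumulative_metastasis_intensity(met, growth, 1.0, 2.0), 2 - n_mid
                )
            ) * survival_interval_prob(m1, oracle_theta, 1.0, 2.0, n_mid, 2 - n_mid)
            total += t1 * t2
        expected = math.log(total) + float(
            size_observation_loglik(params["S0"], 0.066, params["sigma_S"])
        ) + float(
            size_observation_loglik(float(growth.volume(2.0)), 0.12, params["sigma_S"])
        )
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_missing_count_at_death_is_finite_sum(self, m1, oracle_theta):
        """A missing count on the death row marginalises the increment up
        to the cut-off; the summed value matches direct enumeration."""
        rec = self._record([0.0, 1.5], [0.066, np.nan], [0, np.nan], [0, 1])
        got = patient_loglik(m1, oracle_theta, rec, M_max=6).loglik
        from oncotraj.intensities import cumulative_metastasis_intensity

        params = m1.params(oracle_theta)
        growth = m1.build_growth(params)
        met = m1.build_metastasis(params)
        lam = cumulative_metastasis_intensity(met, growth, 0.0, 1.5)
        total = sum(
            math.exp(metastasis_increment_loglik(lam, m))
            * death_interval_density(m1, oracle_theta, 0.0, 1.5, 0, m)
            for m in range(7)
        )
        expected = math.log(total) + float(
            size_observation_loglik(params["S0"], 0.066, params["sigma_S"])
        )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_masking_consistency_contains_true_path(self, m1, oracle_theta):
        """The marginalised likelihood exceeds any single-path term."""
        full = self._record([0.0, 1.0, 2.0], [0.066, 0.08, 0.12], [0, 1, 2], [0, 0, 0])
        masked = self._record(
            [0.0, 1.0, 2.0], [0.066, 0.08, 0.12], [0, np.nan, 2], [0, 0, 0]
        )
        # size at the masked visit stays observed; compare process parts via
        # explicit enumeration over the hidden count
        ll_full = patient_loglik(m1, oracle_theta, full).loglik
        ll_masked = patient_loglik(m1, oracle_theta, masked).loglik
        assert ll_masked >= ll_full - 1e-12

    def test_decreasing_counts_rejected(self, m1, oracle_theta):
        with pytest.raises(ValueError):
            self._record([0.0, 1.0], [0.06, 0.08], [2, 1], [0, 0])

    def test_death_not_last_rejected(self, m1, oracle_theta):
        with pytest.raises(ValueError):
            self._record([0.0, 1.0], [0.06, 0.08], [0, 0], [1, 0])


class TestCohortLikelihood:
    def test_additivity_over_patients(self, m1, m1_cohort, oracle_theta):
        total = -cohort_negloglik(m1, m1.true_theta, m1_cohort)
        parts = sum(
            patient_loglik(m1, m1.true_theta, rec, M_max=None).loglik
            for rec in m1_cohort
        )
        assert total == pytest.approx(parts, rel=1e-9)

    def test_duplicated_cohort_doubles_value(self, m1, design):
        coh = simulate_cohort(m1, 10, design, seed=3)
        doubled = Cohort(
            records=[
                PatientRecord(
                    patient_id=f"{r.patient_id}-{k}",
                    times=r.times,
                    size_obs=r.size_obs,
                    n_metastases=r.n_metastases,
                    death=r.death,
                    covariates=r.covariates,
                )
                for k in (0, 1)
                for r in coh
            ]
        )
        assert cohort_negloglik(m1, None, doubled) == pytest.approx(
            2 * cohort_negloglik(m1, None, coh), rel=1e-12
        )

    def test_impossible_theta_gives_inf(self, m1, m1_cohort):
        # zero seeding rates cannot explain observed metastases
        theta = dict(m1.true_theta, m_basal=0.0, m_size=0.0)
        assert cohort_negloglik(m1, theta, m1_cohort) == math.inf

    @pytest.mark.parametrize("model_name", ["m1", "m2"])
    def test_analytic_equals_cubature_on_random_parameters(self, model_name, design):
        """Closed-form and nested-cubature cohort likelihoods coincide on
        random parameter draws (relative 1e-6)."""
        model = get_model(model_name)
        coh = simulate_cohort(model, 25, design, seed=41)
        cl = CohortLikelihood(model, coh)
        rng = np.random.default_rng(17)
        lo, hi = model.log_bounds_arrays()
        for _ in range(10):
            theta = np.exp(lo + (hi - lo) * rng.random(lo.size))
            a = cl.loglik_value(theta, method="closed_form").loglik
            b = cl.loglik_value(theta, method="cubature").loglik
            assert a == pytest.approx(b, rel=1e-6)

    def test_masked_cohort_likelihood_is_finite(self, m1, design):
        from oncotraj import mask_missing

        coh = simulate_cohort(m1, 30, design, seed=43)
        masked = mask_missing(coh, 0.3, 0.2, 0.2, seed=44)
        val = cohort_negloglik(m1, None, masked)
        assert np.isfinite(val)
        assert val < cohort_negloglik(m1, None, coh)  # fewer terms, less info

    def test_breakdown_sums_to_total(self, m1, m1_cohort):
        cl = CohortLikelihood(m1, m1_cohort)
        v = cl.loglik_value(None)
        assert v.loglik == pytest.approx(
            v.observation + v.metastasis + v.survival_death, rel=1e-12
        )
        assert v.loglik == pytest.approx(float(np.sum(v.per_patient)), rel=1e-12)

    def test_m5_closed_form_matches_per_interval_composition(self):
        """Piecewise growth (treatment mid-interval) against the scalar
        interval primitives."""
        m5 = get_model("m5")
        cov = {"treatment_start": 1.4, "obese": 1}
        params = m5.params(None)
        growth = m5.build_growth(params, cov)
        rec = PatientRecord(
            patient_id="p0",
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            size_obs=np.array([0.07, float(growth.volume(1.0)), np.nan, float(growth.volume(3.0))]),
            n_metastases=np.array([0.0, 0.0, 1.0, 1.0]),
            death=np.array([0, 0, 0, 0]),
            covariates=cov,
        )
        got = patient_loglik(m5, None, rec).loglik
        from oncotraj.intensities import cumulative_metastasis_intensity

        met = m5.build_metastasis(params)
        expected = 0.0
        for t, s in zip(rec.times, rec.size_obs):
            if np.isfinite(s):
                expected += float(
                    size_observation_loglik(float(growth.volume(t)), s, params["sigma_S"])
                )
        for (ta, tb, n_prev, m) in [(0.0, 1.0, 0, 0), (1.0, 2.0, 0, 1), (2.0, 3.0, 1, 0)]:
            lam = cumulative_metastasis_intensity(met, growth, ta, tb)
            expected += float(metastasis_increment_loglik(lam, m))
            expected += math.log(
                survival_interval_prob(m5, None, ta, tb, n_prev, m, covariates=cov)
            )
        assert got == pytest.approx(expected, rel=1e-10)
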