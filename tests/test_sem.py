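"""SEM maximum likelihood: recovery, equivalence with the LMM subclass,
delta-method inference and fit statistics."""

import numpy as np
import pytest

import medlongsim as m
from medlongsim.sem import MediatedGrowthSEM


@pytest.fixture(scope="module")
def sem_fit_large(medium_equal_params):
    ds = m.simulate_dataset(medium_equal_params, 20_000, m.ErrorSpec(), seed=2)
    return m.fit_sem(ds), medium_equal_params


class TestParameterRecovery:
    def test_all_parameters_within_2se_at_large_n(self, sem_fit_large):
        res, p = sem_fit_large
        assert res.converged
        truth = {
            "alpha1": p.alpha1, "alpha2": p.alpha2, "alpha3": p.alpha3,
            "gamma11": p.gamma11, "gamma21": p.gamma21, "gamma31": p.gamma31,
            "gamma13": p.gamma13, "gamma23": p.gamma23, "gamma33": p.gamma33,
            "b13": p.b13, "b23": p.b23,
            "psi11": p.psi[0, 0], "psi12": p.psi[0, 1],
            "psi22": p.psi[1, 1], "psi33": p.psi[2, 2],
            "sigma2": p.sigma2,
        }
        for name, est, se in zip(res.param_names, res.params, res.bse):
            assert abs(est - truth[name]) < 2 * se, (name, est, truth[name], se)

    def test_mean_recovery_over_replicates(self, medium_equal_params):
        """Average total-effect estimate over 150 cohorts of n=250 is within
        3 Monte-Carlo SEs of the generating value."""
        p = medium_equal_params
        ests = []
        for i in range(150):
            ds = m.simulate_dataset(p, 250, m.ErrorSpec(), seed=3000 + i)
            res = MediatedGrowthSEM(ds).fit(compute_vcov=False)
            if res.converged:
                ests.append(res.estimates["gamma13"]
                            + res.estimates["b13"] * res.estimates["gamma33"])
        ests = np.array(ests)
        assert len(ests) >= 145
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - m.total_effect(p)) < 3 * mc_se

    def test_no_mediation_data_recovers_direct_effect(self, base_params):
        from dataclasses import replace
        p = replace(base_params, gamma13=0.5, b13=0.0, b23=0.0)
        ds = m.simulate_dataset(p, 5000, m.ErrorSpec(), seed=44)
        res = m.fit_sem(ds)
        est, se = res.total_effect()
        assert est == pytest.approx(0.5, abs=2.5 * se)


class TestSEMvsLMM:
    def test_total_effect_near_identical_to_lmm2(self, medium_equal_params):
        diffs = []
        for i in range(8):
            ds = m.simulate_dataset(medium_equal_params, 500, m.ErrorSpec(),
                                    seed=600 + i)
            e_sem, _ = m.fit_sem(ds).total_effect()
            e_lmm = m.fit_lmm(ds).total_effect_estimate
            diffs.append(e_sem - e_lmm)
        diffs = np.array(diffs)
        assert np.max(np.abs(diffs)) < 0.05
        assert abs(diffs.mean()) < 0.01

    def test_likelihood_equivalence_with_lmm2(self, medium_equal_params):
        """The mediator-free SEM (gamma21 = gamma23 = 0) and the random
        intercept/slope LMM are the same marginal model; their maximized
        likelihoods coincide."""
        for i in range(3):
            ds = m.simulate_dataset(medium_equal_params, 200, m.ErrorSpec(),
                                    seed=700 + i)
            lmm = m.fit_lmm(ds)
            sem = MediatedGrowthSEM(
                ds, include_mediator=False,
                fixed={"gamma21": 0.0, "gamma23": 0.0},
            ).fit(compute_vcov=False)
            assert sem.llf == pytest.approx(lmm.llf, abs=1e-6)

    def test_se_shrinks_like_inverse_sqrt_n(self, medium_equal_params):
        ses = {}
        for n in (250, 1000, 4000):
            ds = m.simulate_dataset(medium_equal_params, n, m.ErrorSpec(),
                                    seed=800)
            ses[n] = m.fit_sem(ds).total_effect_se
        assert ses[250] > ses[1000] > ses[4000]
        assert ses[250] / ses[1000] == pytest.approx(2.0, rel=0.25)
        assert ses[1000] / ses[4000] == pytest.approx(2.0, rel=0.25)


class TestDeltaMethod:
    def test_no_mediation_reduces_to_direct_se(self):
        names = ["gamma13", "b13", "gamma33"]
        est = {"gamma13": 0.4, "b13": 0.0, "gamma33": 0.0}
        V = np.diag([0.09, 1.0, 1.0])
        e, se = m.delta_total_effect(est, V, names)
        assert e == pytest.approx(0.4)
        assert se == pytest.approx(0.3)

    def test_diagonal_vcov_plugin(self):
        names = ["gamma13", "b13", "gamma33"]
        est = {"gamma13": 0.1, "b13": 0.5, "gamma33": 0.3}
        v = 0.04
        _, se = m.delta_total_effect(est, v * np.eye(3), names)
        assert se == pytest.approx(np.sqrt(v * (1 + 0.3**2 + 0.5**2)))

    def test_missing_coefficient_rejected(self):
        with pytest.raises(ValueError, match="does not cover"):
            m.delta_total_effect({"gamma13": 0.1}, np.eye(1), ["gamma13"])

    def test_matches_bootstrap_se(self, medium_equal_params):
        """Nonparametric bootstrap of the SEM total effect on one fixed
        n=250 cohort reproduces the delta-method SE within 10%."""
        ds = m.simulate_dataset(medium_equal_params, 250, m.ErrorSpec(),
                                seed=55)
        res = m.fit_sem(ds)
        _, se_delta = res.total_effect()
        rng = np.random.default_rng(56)
        boots = []
        for _ in range(400):
            idx = rng.integers(0, ds.n_subjects, ds.n_subjects)
            bs = m.TrialDataset(z1=ds.z1[idx], z2=ds.z2[idx], x=ds.x[idx],
                                y=ds.y[idx], times=ds.times)
            r = MediatedGrowthSEM(bs).fit(compute_vcov=False)
            if r.converged:
                e = (r.estimates["gamma13"]
                     + r.estimates["b13"] * r.estimates["gamma33"])
                boots.append(e)
        se_boot = np.std(boots, ddof=1)
        assert se_boot == pytest.approx(se_delta, rel=0.10)


class TestWaldSummary:
    def test_zero_estimate_never_rejected(self):
        s = m.wald_summary(0.0, 1.0)
        assert s.p == pytest.approx(1.0)
        assert not s.reject

    def test_rejection_boundary(self):
        s = m.wald_summary(1.959964 * 0.5, 0.5)
        assert s.p == pytest.approx(0.05, abs=1e-5)
        assert s.ci_low == pytest.approx(0.0, abs=1e-5)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            m.wald_summary(1.0, 0.0)

    def test_type_i_error_calibration(self, base_params):
        """Under a zero total effect the Wald test rejects at ~alpha."""
        from dataclasses import replace
        p = replace(base_params, gamma13=0.0, b13=0.0, b23=0.0, gamma33=0.0)
        rejections = []
        for i in range(40):
            ds = m.simulate_dataset(p, 200, m.ErrorSpec(), seed=900 + i)
            res = m.fit_lmm(ds)
            rejections.append(res.total_effect_wald().reject)
        assert np.mean(rejections) < 0.2


class TestFitStatistics:
    def test_rmsea_formula_boundaries(self):
        assert m.rmsea(33.0, 33, 250) == 0.0
        assert m.rmsea(20.0, 33, 250) == 0.0  # chi2 < df floors at zero
        assert m.rmsea(66.0, 33, 250) == pytest.approx(
            np.sqrt(33.0 / (33 * 249)))

    def test_information_criteria_arithmetic(self, small_dataset):
        res = m.fit_sem(small_dataset)
        stats = res.fit_statistics()
        k = res.n_params
        assert stats.aic == pytest.approx(stats.neg2loglik + 2 * k)
        assert stats.bic == pytest.approx(
            stats.neg2loglik + k * np.log(small_dataset.n_subjects))

    def test_saturated_df_and_good_fit_at_truth(self, medium_equal_params):
        """A correctly specified SEM at large n: df = 49 - 16 = 33,
        chi-square near its df, small RMSEA and SRMR."""
        ds = m.simulate_dataset(medium_equal_params, 20_000, m.ErrorSpec(),
                                seed=66)
        stats = m.fit_sem(ds).fit_statistics()
        assert stats.df == 33
        assert stats.chi_square < 80.0
        assert stats.rmsea < 0.05
        assert stats.srmr < 0.02

    def test_vcov_psd_on_converged_fit(self, small_dataset):
        res = m.fit_sem(small_dataset)
        assert res.converged
        assert np.min(np.linalg.eigvalsh(res.vcov)) > 0
        assert res.total_effect_se > 0

    def test_summary_mentions_total_effect(self, small_dataset):
        text = m.fit_sem(small_dataset).summary()
        assert "total effect" in text
        assert "gamma33" in text
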