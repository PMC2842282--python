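"""Model-implied moments, total-effect algebra and effect-size calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import medlongsim as m
from medlongsim.parameters import _sd_total

from conftest import random_params


def brute_force_moments(params: m.SEMParameters, z1: float, z2: float):
    """Independent oracle: build the 9-dim joint (zeta, eps) covariance and
    push it through the structural/measurement linear maps."""
    inv = np.linalg.inv(np.eye(3) - params.B)
    lam = params.Lambda
    z = np.array([z1, z2])
    mean = lam @ inv @ (params.alpha + params.Gamma @ z)
    # v = Lam inv zeta + E eps, with E selecting eps_j for Y_j and 0 for x
    L = np.zeros((7, 9))
    L[:, :3] = lam @ inv
    L[:6, 3:] = np.eye(6)
    C = np.zeros((9, 9))
    C[:3, :3] = params.psi
    C[3:, 3:] = params.sigma2 * np.eye(6)
    return mean, L @ C @ L.T


class TestLatentMoments:
    def test_zero_b_gives_psi(self, base_params):
        _, cov = m.latent_moments(base_params, 0.5, 1.0)
        assert np.allclose(cov, base_params.psi)

    def test_zero_coefficients_give_zero_means(self):
        p = m.SEMParameters(gamma11=0, gamma21=0, gamma31=0,
                            gamma13=0, gamma23=0, gamma33=0)
        for z1, z2 in [(0, 0), (1.3, 1.0), (-2.0, 0.0)]:
            mean, _ = m.latent_moments(p, z1, z2)
            assert np.allclose(mean, 0.0)

    def test_mediator_feedback_variance(self):
        # b13 = 1, Psi = I: Var(U1) = 2, Cov(U1, U3) = 1, Var(U3) = 1
        p = m.SEMParameters(b13=1.0, psi=np.eye(3))
        _, cov = m.latent_moments(p, 0.0, 0.0)
        assert cov[0, 0] == pytest.approx(2.0)
        assert cov[0, 2] == pytest.approx(1.0)
        assert cov[2, 2] == pytest.approx(1.0)


class TestImpliedOutcomeMoments:
    def test_pure_noise_covariance(self):
        p = m.SEMParameters(psi=np.zeros((3, 3)), sigma2=1.0)
        _, cov = m.implied_outcome_moments(p, 0.3, 1.0)
        assert np.allclose(cov[:6, :6], np.eye(6))
        assert np.allclose(cov[6, :], 0.0)

    def test_outcome_mediator_covariance_formula(self, medium_equal_params):
        p = medium_equal_params
        _, cov = m.implied_outcome_moments(p, 0.0, 0.0)
        psi33 = p.psi[2, 2]
        for j, t in enumerate(p.times):
            expected = p.b13 * psi33 + t * p.b23 * psi33
            assert cov[j, 6] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_joint(self, seed):
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        z1, z2 = rng.normal(), float(rng.integers(0, 2))
        mean, cov = m.implied_outcome_moments(p, z1, z2)
        mean_o, cov_o = brute_force_moments(p, z1, z2)
        assert np.allclose(mean, mean_o, atol=1e-12)
        assert np.allclose(cov, cov_o, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_covariances_symmetric_psd(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = random_params(rng)
        _, lcov = m.latent_moments(p, 0.7, 1.0)
        _, ocov = m.implied_outcome_moments(p, 0.7, 1.0)
        for cov in (lcov, ocov):
            assert np.allclose(cov, cov.T)
            assert np.min(np.linalg.eigvalsh(cov)) > -1e-10


class TestTotalEffect:
    def test_intercept_sum_of_paths(self):
        p = m.SEMParameters(gamma13=0.3, b13=0.6, gamma33=0.5)
        assert m.total_effect(p, "intercept") == pytest.approx(0.6)

    def test_no_mediation_reduces_to_direct(self):
        p = m.SEMParameters(gamma13=0.3, b13=0.0, gamma33=0.5)
        assert m.total_effect(p) == pytest.approx(0.3)

    def test_slope_component(self):
        p = m.SEMParameters(gamma23=0.0, b23=0.4, gamma33=0.5)
        assert m.total_effect(p, "slope") == pytest.approx(0.2)

    def test_unknown_component_rejected(self, base_params):
        with pytest.raises(ValueError):
            m.total_effect(base_params, "quadratic")

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_to_variance_components(self, seed):
        rng = np.random.default_rng(300 + seed)
        p = random_params(rng)
        from dataclasses import replace
        q = replace(p, psi=np.diag([2.0, 2.0, 2.0]), sigma2=9.0)
        assert m.total_effect(p) == m.total_effect(q)
        assert m.total_effect(p, "slope") == m.total_effect(q, "slope")


class TestEffectSize:
    def test_direct_only_standardizes_by_psi11(self):
        p = m.SEMParameters(gamma13=0.5, b13=0.0, psi=np.eye(3))
        assert m.effect_size(p) == pytest.approx(0.5)

    def test_equal_split_worked_example(self):
        # c / sqrt(c^2 + 1) = 0.5 at c = 1/sqrt(3) = 0.5774 with b13 = c
        c = 1.0 / np.sqrt(3.0)
        p = m.SEMParameters(gamma13=c / 2, b13=c, gamma33=0.5, psi=np.eye(3))
        assert m.effect_size(p) == pytest.approx(0.5, abs=1e-12)

    def test_linearity_in_direct_effect(self):
        p1 = m.SEMParameters(gamma13=0.2, b13=0.0)
        p2 = m.SEMParameters(gamma13=0.4, b13=0.0)
        assert m.effect_size(p2) == pytest.approx(2 * m.effect_size(p1))

    def test_zero_variance_rejected(self):
        p = m.SEMParameters(psi=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            m.effect_size(p)


class TestCalibration:
    def test_pure_direct_closed_form(self, base_params):
        t = m.EffectTarget(0.4, "direct", w=1.0)
        p = m.calibrate_effects(t, base_params)
        assert p.b13 == pytest.approx(0.0)
        assert p.gamma13 == pytest.approx(0.4 * np.sqrt(base_params.psi[0, 0]))

    def test_equal_split_worked_example(self, base_params):
        p = m.calibrate_effects(m.EffectTarget(0.5, "equal"), base_params)
        assert m.total_effect(p) == pytest.approx(0.57735, abs=1e-4)
        assert p.gamma13 == pytest.approx(0.28868, abs=1e-4)
        assert p.b13 == pytest.approx(0.57735, abs=1e-4)

    @given(
        e=st.floats(0.05, 0.9),
        split=st.sampled_from(["equal", "direct", "indirect"]),
        component=st.sampled_from(["intercept", "slope"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip(self, e, split, component):
        base = m.SEMParameters()
        # indirect-heavy splits cap the reachable standardized effect
        target = m.EffectTarget(e, split, component)
        try:
            p = m.calibrate_effects(target, base)
        except ValueError:
            assert split == "indirect" or e > 0.9
            return
        assert m.effect_size(p, component) == pytest.approx(e, abs=1e-8)

    def test_monotone_in_target(self, base_params):
        totals = [
            abs(m.total_effect(m.calibrate_effects(
                m.EffectTarget(e, "equal"), base_params)))
            for e in (0.2, 0.35, 0.5, 0.8)
        ]
        assert np.all(np.diff(totals) > 0)

    def test_slope_target_zeroes_intercept_paths(self, base_params):
        p = m.calibrate_effects(m.EffectTarget(0.5, "equal", "slope"),
                                base_params)
        assert p.gamma13 == 0.0 and p.b13 == 0.0
        assert m.effect_size(p, "slope") == pytest.approx(0.5, abs=1e-8)

    def test_indirect_without_mediator_path_fails(self):
        base = m.SEMParameters(gamma33=0.0)
        with pytest.raises(ValueError, match="gamma33"):
            m.calibrate_effects(m.EffectTarget(0.5, "indirect"), base)

    def test_sd_total_definition(self):
        p = m.SEMParameters(b13=0.6, psi=np.diag([1.0, 0.25, 2.0]))
        assert _sd_total(p, "intercept") == pytest.approx(
            np.sqrt(0.36 * 2.0 + 1.0))


class TestSerialization:
    def test_dict_roundtrip(self, medium_equal_params):
        d = medium_equal_params.to_dict()
        back = m.SEMParameters.from_dict(d)
        assert back.to_dict() == d

    def test_json_roundtrip(self, tmp_path, medium_equal_params):
        path = tmp_path / "params.json"
        medium_equal_params.to_json(path)
        back = m.SEMParameters.from_json(path)
        assert np.allclose(back.psi, medium_equal_params.psi)
        assert back.b13 == pytest.approx(medium_equal_params.b13)


class TestInvariants:
    def test_bad_times_rejected(self):
        with pytest.raises(ValueError):
            m.SEMParameters(times=np.array([0, 1, 2, 3, 4]))
        with pytest.raises(ValueError):
            m.SEMParameters(times=np.array([0, 2, 1, 3, 4, 5]))

    def test_non_psd_psi_rejected(self):
        psi = np.diag([1.0, 1.0, 1.0])
        psi[0, 1] = psi[1, 0] = 1.5
        with pytest.raises(ValueError):
            m.SEMParameters(psi=psi)

    def test_negative_sigma2_rejected(self):
        with pytest.raises(ValueError):
            m.SEMParameters(sigma2=-0.1)
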