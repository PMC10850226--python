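"""Natural-effect odds ratios, delta-method uncertainty, proportion mediated."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import frailmed as fm
from frailmed.glm import MediatorFit, OutcomeFit
from frailmed.mediation import (
    MediationSpec,
    bootstrap_mediation,
    delta_method_se,
    estimate,
    natural_effects,
    pm_inference,
    proportion_mediated,
)
from frailmed.mediation import test_interaction as interaction_report


def _med(beta0=0.0, beta1=0.002, beta2=(), sigma2=0.002, vcov=None):
    k = 2 + len(beta2)
    return MediatorFit(
        beta0=beta0, beta1=beta1, beta2=np.asarray(beta2, float), sigma2=sigma2,
        vcov=np.zeros((k, k)) if vcov is None else np.asarray(vcov, float),
        n=100, column_names=tuple(["const", "age"] + [f"c{i}" for i in range(len(beta2))]),
    )


def _out(theta0=-3.0, theta1=0.02, theta2=5.0, theta3=None, theta4=(), vcov=None):
    interaction = theta3 is not None
    k = (4 if interaction else 3) + len(theta4)
    names = ["const", "age", "frailty_index"]
    if interaction:
        names.append("age:frailty_index")
    names += [f"c{i}" for i in range(len(theta4))]
    return OutcomeFit(
        theta0=theta0, theta1=theta1, theta2=theta2,
        theta3=theta3 if interaction else 0.0,
        theta4=np.asarray(theta4, float),
        vcov=np.zeros((k, k)) if vcov is None else np.asarray(vcov, float),
        loglik=0.0, converged=True, interaction=interaction, n=100,
        column_names=tuple(names),
    )


SPEC = MediationSpec(a=68.7, a_star=67.7)


class TestNaturalEffects:
    def test_severed_mediator_path_gives_unit_nie(self):
        te, nde, nie = natural_effects(_med(), _out(theta1=0.05, theta2=0.0), SPEC)
        assert np.exp(nde) == pytest.approx(np.exp(0.05))
        assert np.exp(nie) == 1.0

    def test_no_exposure_mediator_path_gives_unit_nie(self):
        te, nde, nie = natural_effects(_med(beta1=0.0), _out(theta2=5.0), SPEC)
        assert np.exp(nie) == 1.0

    def test_product_form_without_interaction(self):
        te, nde, nie = natural_effects(
            _med(beta1=0.002), _out(theta1=0.02, theta2=5.0), SPEC
        )
        assert nie == pytest.approx(0.01)
        assert np.exp(nie) == pytest.approx(1.01005, abs=1e-5)
        assert nde == pytest.approx(0.02)

    def test_interaction_formula_hand_evaluated(self):
        """theta3 != 0 case against an independent hand evaluation."""
        med = _med(beta0=-0.05, beta1=0.002, beta2=(0.01,), sigma2=0.0016)
        out = _out(theta1=0.02, theta2=5.0, theta3=0.1, theta4=(0.3,))
        spec = MediationSpec(a=69.0, a_star=67.0, interaction=True, c_cond=[2.0])
        te, nde, nie = natural_effects(med, out, spec)
        kappa = -0.05 + 0.002 * 67.0 + 0.01 * 2.0 + 5.0 * 0.0016
        expect_nde = (0.02 + 0.1 * kappa) * 2.0 + 0.5 * 0.1**2 * 0.0016 * (69.0**2 - 67.0**2)
        expect_nie = (5.0 * 0.002 + 0.1 * 0.002 * 69.0) * 2.0
        assert nde == pytest.approx(expect_nde, rel=1e-12)
        assert nie == pytest.approx(expect_nie, rel=1e-12)
        assert te == nde + nie

    def test_interaction_spec_requires_interaction_fit(self):
        spec = MediationSpec(a=1.0, a_star=0.0, interaction=True, c_cond=[])
        with pytest.raises(ValueError, match="interaction"):
            natural_effects(_med(), _out(), spec)

    def test_invariant_to_conditioning_without_interaction(self):
        med, out = _med(beta2=(0.1, -0.2)), _out(theta4=(0.5, 0.5))
        res1 = natural_effects(med, out, MediationSpec(a=1, a_star=0, c_cond=[0, 0]))
        res2 = natural_effects(med, out, MediationSpec(a=1, a_star=0, c_cond=[9, -4]))
        assert res1 == res2

    @given(
        st.floats(-0.05, 0.05), st.floats(-0.005, 0.005), st.floats(-8, 8),
        st.floats(0.0, 0.15),
    )
    def test_identity_te_equals_nde_plus_nie(self, t1, b1, t2, t3):
        med = _med(beta1=b1, sigma2=0.001)
        out = _out(theta1=t1, theta2=t2, theta3=t3)
        spec = MediationSpec(a=70.0, a_star=65.0, interaction=True, c_cond=[])
        te, nde, nie = natural_effects(med, out, spec)
        assert te == nde + nie  # exact, not approximate


class TestDeltaMethod:
    def test_zero_covariance_collapses_cis(self):
        est = estimate(_med(), _out(), SPEC)
        assert est.se_log_nde == est.se_log_nie == 0.0
        assert est.ci_nde == (est.or_nde, est.or_nde)
        assert est.ci_pm == (est.pm, est.pm)

    def test_product_special_case_closed_form(self):
        """Without interaction, SE(log NIE) is the product-of-coefficients
        delta form sqrt(t2^2 v_b1 + b1^2 v_t2) |delta a|."""
        v_b1, v_t2 = 4e-9, 1.2
        med_vcov = np.zeros((2, 2)); med_vcov[1, 1] = v_b1
        out_vcov = np.zeros((3, 3)); out_vcov[2, 2] = v_t2
        med = _med(vcov=med_vcov)
        out = _out(vcov=out_vcov)
        spec = MediationSpec(a=70.0, a_star=65.0)
        _, _, se_nie, cov = delta_method_se(med, out, spec)
        expected = np.sqrt(5.0**2 * v_b1 + 0.002**2 * v_t2) * 5.0
        assert se_nie == pytest.approx(expected, rel=1e-12)
        assert cov[0, 1] == 0.0

    def test_se_within_10pct_of_bootstrap(self):
        params = fm.rare_outcome_params(n=3000, prevalence=0.05)
        design = fm.simulate_design(params, seed=0)
        est = fm.NaturalEffectsMediator().fit(design)
        boot = bootstrap_mediation(design, est.spec_, B=400, seed=0)
        for key, se in (
            ("log_nde", est.estimates_.se_log_nde),
            ("log_nie", est.estimates_.se_log_nie),
        ):
            assert se == pytest.approx(boot[key]["se"], rel=0.10)


class TestProportionMediated:
    def test_edge_cases(self):
        assert proportion_mediated(1.5, 1.0) == 0.0
        assert proportion_mediated(1.0, 1.3) == pytest.approx(1.0)
        assert proportion_mediated(1.02, 1.01) == pytest.approx(
            1.02 * 0.01 / (1.02 * 1.01 - 1), rel=1e-12
        )

    def test_null_total_effect_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            proportion_mediated(1.0, 1.0)

    def test_inference_gradient_matches_finite_differences(self):
        cov = np.array([[4e-4, 1e-4], [1e-4, 2.5e-4]])
        l1, l2 = 0.02, 0.01
        pm, se, raw, trunc, p = pm_inference(l1, l2, cov)

        def f(a, b):
            return proportion_mediated(float(np.exp(a)), float(np.exp(b)))

        h = 1e-7
        g = np.array([(f(l1 + h, l2) - f(l1 - h, l2)) / (2 * h),
                      (f(l1, l2 + h) - f(l1, l2 - h)) / (2 * h)])
        assert se == pytest.approx(float(np.sqrt(g @ cov @ g)), rel=1e-5)
        assert raw[0] <= pm <= raw[1]
        assert trunc[0] >= 0.0 and trunc[1] <= 1.0

    def test_zero_covariance_collapses(self):
        pm, se, raw, trunc, p = pm_inference(0.02, 0.01, np.zeros((2, 2)))
        assert se == 0.0 and raw == (pm, pm)


class TestBootstrap:
    def test_seeded_determinism(self, rare_params):
        params = fm.rare_outcome_params(n=800, prevalence=0.08)
        design = fm.simulate_design(params, seed=1)
        spec = MediationSpec(a=68.7, a_star=67.7)
        b1 = bootstrap_mediation(design, spec, B=200, seed=9)
        b2 = bootstrap_mediation(design, spec, B=200, seed=9)
        assert b1 == b2

    def test_null_mediation_ci_covers_unity(self):
        params = fm.rare_outcome_params(n=2000, prevalence=0.08)
        params = replace(
            params, beta1=0.0, beta0=0.115, theta2=0.0
        ).with_calibrated_intercept(0.08)
        design = fm.simulate_design(params, seed=3)
        spec = MediationSpec(a=68.7, a_star=67.7)
        boot = bootstrap_mediation(design, spec, B=300, seed=3)
        assert boot["or_nie"]["lo"] <= 1.0 <= boot["or_nie"]["hi"]

    def test_minimum_replicates_enforced(self, fitted_mediation):
        design, est = fitted_mediation
        with pytest.raises(ValueError, match="B >= 200"):
            bootstrap_mediation(design, est.spec_, B=50)


class TestEstimatorInterface:
    def test_fitted_attributes_and_identity(self, fitted_mediation):
        design, est = fitted_mediation
        e = est.estimates_
        assert e.log_te == e.log_nde + e.log_nie  # exact identity
        assert e.or_te == pytest.approx(np.exp(e.log_te))
        assert e.ci_nie[0] <= e.or_nie <= e.ci_nie[1]
        assert est.n_ == design.n
        assert set(est.vif_) == set(est.outcome_fit_.column_names[1:])

    def test_sklearn_param_interface(self):
        est = fm.NaturalEffectsMediator(interaction=True, alpha=0.10)
        assert est.get_params()["alpha"] == 0.10
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05

    def test_prevalence_warning_for_common_outcomes(self):
        params = fm.mortality_demo_params(n=1500)
        design = fm.simulate_design(params, seed=0)
        with pytest.warns(UserWarning, match="prevalence"):
            fm.NaturalEffectsMediator().fit(design)


class TestInteractionReport:
    def test_null_interaction_barely_moves_effects(self):
        params = fm.rare_outcome_params(n=4000, prevalence=0.05)  # theta3 = 0
        design = fm.simulate_design(params, seed=6)
        spec = MediationSpec(a=68.7, a_star=67.7, c_cond=params.covariate_means)
        rep = interaction_report(design, spec)
        assert 0.0 <= rep.wald_p <= 1.0
        assert rep.lr_stat >= 0.0
        # adding a null interaction should not move the effects materially
        assert abs(rep.delta_log_nde) < 5 * rep.without_interaction.se_log_nde
        assert abs(rep.delta_log_nie) < 5 * rep.without_interaction.se_log_nie

    def test_strong_interaction_detected(self):
        params = fm.strong_interaction_params(n=2000)
        design = fm.simulate_design(params, seed=1)
        spec = MediationSpec(a=68.7, a_star=67.7, c_cond=params.covariate_means)
        rep = interaction_report(design, spec)
        assert rep.wald_p < 0.05 and rep.lr_p < 0.05

    def test_identical_variants_give_zero_deltas(self):
        """When the fitted interaction coefficient is exactly zero both
        variants coincide and the effect deltas vanish."""
        med = _med(beta2=(0.0,))
        out0 = _out(theta4=(0.1,))
        out1 = _out(theta3=0.0, theta4=(0.1,))
        spec0 = MediationSpec(a=68.7, a_star=67.7, c_cond=[0.0])
        spec1 = MediationSpec(a=68.7, a_star=67.7, interaction=True, c_cond=[0.0])
        e0 = estimate(med, out0, spec0)
        e1 = estimate(med, out1, spec1)
        assert e1.log_nde - e0.log_nde == 0.0
        assert e1.log_nie - e0.log_nie == 0.0
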