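"""Joint density of the CE/RE hierarchy, and agreement between the
readable reference evaluation and the compiled sampling path."""

import math

import numpy as np
import pytest
from scipy import stats

from aemeta.core import ArmAggregate
from aemeta.hierarchy import (
    HistoricalParams,
    ModelSpec,
    ParameterState,
    TrialParams,
    log_likelihood,
    log_posterior_unnormalized,
    log_prior,
)
from aemeta.priors import PriorSpec, named_prior
from aemeta._compile import CompiledModel
from tests.test_core import brute_force_log_likelihood


def toy_dataset():
    return [
        ArmAggregate("a", 0, 40, 4, 10, 1, 1.0),
        ArmAggregate("a", 1, 50, 9, 12, 2, 1.0),
        ArmAggregate("b", 0, 30, 2, 6, 0, 2.0),
        ArmAggregate("b", 1, 30, 5, 8, 1, 2.0),
        ArmAggregate("h1", 0, 60, 6, 15, 2, 0.5, historical=True),
    ]


def toy_state(re=False):
    s = ParameterState(
        q0=0.3, q1=0.25, phi=0.4, eta=0.2 if re else None,
        nu1=-1.8, sigma1=0.5, nu2=-1.2, sigma2=0.4, nu3=-1.0, sigma3=0.3,
        trials={
            "a": TrialParams(-1.6, -1.3, -1.1, 0.5 if re else 0.4),
            "b": TrialParams(-2.0, -1.0, -0.8, 0.3 if re else 0.4),
        },
        historical={"h1": HistoricalParams(-1.7, -1.4)},
    )
    return s


class TestLogPrior:
    def test_point_mass_hyperpriors_leave_hierarchy_only(self):
        state = toy_state()
        spec = ModelSpec(
            effect_type="common", anchor="control",
            priors={k: PriorSpec.point_mass(getattr(state, k))
                    for k in ("nu1", "sigma1", "nu2", "sigma2", "nu3", "sigma3",
                              "q0", "q1", "phi")})
        lp = log_prior(state, spec)
        expect = 0.0
        for tp in state.trials.values():
            expect += stats.norm.logpdf(tp.log_lambda_anchor, state.nu1, state.sigma1)
            expect += stats.norm.logpdf(tp.log_mu0, state.nu2, state.sigma2)
            expect += stats.norm.logpdf(tp.log_mu1, state.nu3, state.sigma3)
        hp = state.historical["h1"]
        expect += stats.norm.logpdf(hp.log_lambda0, state.nu1, state.sigma1)
        expect += stats.norm.logpdf(hp.log_mu0, state.nu2, state.sigma2)
        assert lp == pytest.approx(expect, abs=1e-12)

    def test_full_vague_spec_term_by_term(self):
        state = toy_state(re=True)
        spec = ModelSpec.vague("random", phi_prior="cauchy-0.37", eta_prior="hn-0.5")
        expect = 0.0
        expect += stats.norm.logpdf(state.nu1, 0, 100) + stats.halfnorm.logpdf(state.sigma1, 0, 100)
        expect += stats.norm.logpdf(state.nu2, 0, 100) + stats.halfnorm.logpdf(state.sigma2, 0, 100)
        expect += stats.norm.logpdf(state.nu3, 0, 100) + stats.halfnorm.logpdf(state.sigma3, 0, 100)
        expect += stats.beta.logpdf(state.q0, 0.5, 0.5) + stats.beta.logpdf(state.q1, 0.5, 0.5)
        expect += stats.cauchy.logpdf(state.phi, 0, 0.37)
        expect += stats.halfnorm.logpdf(state.eta, 0, 0.5)
        for tp in state.trials.values():
            expect += stats.norm.logpdf(tp.log_lambda_anchor, state.nu1, state.sigma1)
            expect += stats.norm.logpdf(tp.log_mu0, state.nu2, state.sigma2)
            expect += stats.norm.logpdf(tp.log_mu1, state.nu3, state.sigma3)
            expect += stats.norm.logpdf(tp.phi_i, state.phi, state.eta)
        hp = state.historical["h1"]
        expect += stats.norm.logpdf(hp.log_lambda0, state.nu1, state.sigma1)
        expect += stats.norm.logpdf(hp.log_mu0, state.nu2, state.sigma2)
        assert log_prior(state, spec) == pytest.approx(expect, rel=1e-12)

    def test_negative_scale_is_rejected(self):
        state = toy_state(re=True)
        state.sigma1 = -0.1
        spec = ModelSpec.vague("random")
        assert log_prior(state, spec) == -math.inf
        assert log_posterior_unnormalized(state, toy_dataset(), spec) == -math.inf


class TestLogLikelihood:
    def test_empty_dataset(self):
        assert log_likelihood(toy_state(), [], ModelSpec.vague()) == 0.0

    def test_delegates_to_marginalized_arm_likelihood(self):
        # single arm with directly specified category probabilities
        state = ParameterState(q0=0.5, phi=0.0, nu1=0, sigma1=1, nu2=0, sigma2=1,
                               nu3=0, sigma3=1, q1=0.5,
                               trials={"t": TrialParams(-0.7, -0.7, -0.7, 0.0)})
        arm = ArmAggregate("t", 0, 3, 1, 1, 0, 1.0)
        from aemeta.core import ArmRates, category_probabilities
        p = category_probabilities(ArmRates(math.exp(-0.7), math.exp(-0.7), 0.5, 1.0))
        expect = brute_force_log_likelihood(3, 1, 1, 0, p.as_array())
        got = log_likelihood(state, [arm], ModelSpec.vague())
        assert got == pytest.approx(expect, abs=1e-10)

    def test_ce_equals_re_at_zero_heterogeneity(self):
        data = toy_dataset()
        ce_state = toy_state(re=False)
        re_state = toy_state(re=True)
        for tid in re_state.trials:
            re_state.trials[tid].phi_i = ce_state.phi
        re_state.eta = 0.0
        ce = ModelSpec.vague("common")
        re = ModelSpec.vague("random")
        assert log_likelihood(re_state, data, re) == pytest.approx(
            log_likelihood(ce_state, data, ce), rel=1e-12)

    def test_unknown_trial_raises(self):
        arm = ArmAggregate("zzz", 0, 10, 1, 2, 0, 1.0)
        with pytest.raises(KeyError, match="zzz"):
            log_likelihood(toy_state(), [arm], ModelSpec.vague())

    def test_anchor_symmetry(self):
        """Relabelling arms and negating the log-HR leaves the likelihood
        unchanged when the anchoring is switched."""
        data = toy_dataset()[:4]  # two-armed trials only
        state_c = toy_state()
        spec_c = ModelSpec.vague("common", anchor="control")
        ll_c = log_likelihood(state_c, data, spec_c)

        flipped = [ArmAggregate(a.trial_id, 1 - a.arm, a.n, a.y, a.z, a.m, a.tau)
                   for a in data]
        state_t = toy_state()
        state_t.phi = -state_c.phi
        # swap the drop-out parameters along with the arm labels
        for tid, tp in state_c.trials.items():
            state_t.trials[tid] = TrialParams(
                log_lambda_anchor=tp.log_lambda_anchor,
                log_mu0=tp.log_mu1, log_mu1=tp.log_mu0, phi_i=-state_c.phi)
        q0, q1 = state_c.q0, state_c.q1
        state_t.q0, state_t.q1 = q1, q0
        spec_t = ModelSpec.vague("common", anchor="treatment")
        ll_t = log_likelihood(state_t, flipped, spec_t)
        assert ll_t == pytest.approx(ll_c, rel=1e-12)

    def test_translation_property(self):
        """Adding delta to nu1 while shifting the trial-level anchors the
        same way changes the prior but not the likelihood geometry: the
        likelihood depends on the anchors only."""
        data = toy_dataset()
        spec = ModelSpec.vague("common")
        state = toy_state()
        ll0 = log_likelihood(state, data, spec)
        state.nu1 += 0.7  # hyperparameter only: likelihood must not move
        assert log_likelihood(state, data, spec) == pytest.approx(ll0, rel=1e-12)


class TestCompiledEquivalence:
    @pytest.mark.parametrize("effect,anchor", [
        ("common", "control"), ("common", "treatment"),
        ("random", "control"), ("random", "treatment"),
    ])
    def test_compiled_matches_reference(self, effect, anchor, rng):
        data = toy_dataset()
        spec = ModelSpec.vague(effect, anchor=anchor,
                               phi_prior="cauchy-0.37", eta_prior="hn-0.5")
        model = CompiledModel.build(data, spec)
        for _ in range(5):
            theta = model.initial_walkers(rng, 1)[0]
            state = model.unpack_state(theta)
            ref = (log_prior(state, spec) + log_likelihood(state, data, spec)
                   + model.noncentering_jacobian(theta))
            assert model.log_posterior(theta) == pytest.approx(ref, rel=1e-9)

    def test_re_reduces_to_ce_as_eta_vanishes(self, rng):
        """Up to the degenerate phi_i-level terms and the eta prior, the RE
        joint density at phi_i = phi, eta -> 0 equals the CE joint density."""
        data = toy_dataset()
        ce_spec = ModelSpec.vague("common", phi_prior="cauchy-0.37")
        re_spec = ModelSpec.vague("random", phi_prior="cauchy-0.37",
                                  eta_prior="hn-0.5")
        ce_state = toy_state(re=False)
        re_state = toy_state(re=True)
        eps = 1e-8
        re_state.eta = eps
        for tid in re_state.trials:
            re_state.trials[tid].phi_i = re_state.phi
        lp_re = log_posterior_unnormalized(re_state, data, re_spec)
        lp_ce = log_posterior_unnormalized(ce_state, data, ce_spec)
        correction = (len(re_state.trials) * stats.norm.logpdf(0.0, 0.0, eps)
                      + stats.halfnorm.logpdf(eps, 0, 0.5))
        assert lp_re - correction == pytest.approx(lp_ce, rel=1e-9)


class TestModelSpec:
    def test_defaults_fill_in(self):
        spec = ModelSpec.vague("common")
        assert spec.priors["nu1"] == PriorSpec.normal(0, 100)
        assert "eta" not in spec.priors

    def test_rosi_menu(self):
        spec = ModelSpec.rosiglitazone_weakly_informative("random")
        assert spec.priors["nu1"] == PriorSpec.normal(-4.27, math.log(10))
        assert spec.priors["sigma2"] == PriorSpec.half_normal(math.log(10))
        assert spec.priors["eta"] == named_prior("hn-0.5")

    def test_stratified_requires_trial_priors(self):
        with pytest.raises(ValueError, match="trial_level_priors"):
            ModelSpec(effect_type="common", borrowing="stratified")

    def test_unknown_prior_key_rejected(self):
        with pytest.raises(ValueError, match="unknown prior keys"):
            ModelSpec(priors={"zeta": PriorSpec.normal(0, 1)})
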