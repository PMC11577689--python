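import math

import numpy as np
import pytest
from scipy import integrate, stats

import msjoint as mj
from msjoint.likelihood import JointEvaluator, gauss_legendre_rule, theta_from_spec

from conftest import constant_hazard_spec


class TestQuadrature:
    def test_rule_properties(self):
        rule = gauss_legendre_rule(15)
        assert rule.count == 15
        assert np.all(rule.weights > 0)
        assert rule.weights.sum() == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(np.sort(rule.nodes), -np.sort(-rule.nodes)[::-1])

    def test_constant_hazard_exact(self):
        lm = mj.intercept_slope_submodel(beta=(0.0, 0.0))
        tm = mj.TransitionModel((0, 1), mj.WeibullBaseline(1.0, 0.3))
        H = mj.cumulative_hazard(0.0, 5.0, 0.0, [], tm, lm)
        assert H == pytest.approx(1.5, abs=1e-12)

    def test_weibull_closed_form(self):
        # integral of shape*u^(shape-1)*scale over (0, t] is scale * t^shape
        lm = mj.intercept_slope_submodel(beta=(0.0, 0.0))
        tm = mj.TransitionModel((0, 1), mj.WeibullBaseline(2.0, 0.5))
        H = mj.cumulative_hazard(0.0, 2.0, 0.0, [], tm, lm)
        assert H == pytest.approx(0.5 * 2.0**2, abs=1e-10)

    def test_association_modulated_vs_adaptive_quadrature(self):
        lm = mj.intercept_slope_submodel(beta=(0.4, 0.12))
        b = np.array([0.2, -0.05])
        tm = mj.TransitionModel(
            (0, 1), mj.WeibullBaseline(1.6, 0.2), timescale="clock_reset",
            gamma=np.array([0.3]),
            association=mj.AssociationStructure("current_value", 0.8),
        )
        # start strictly after state entry so the u^(shape-1) factor is
        # smooth over the whole integration window
        w = np.array([0.5])
        entry, t0, t1 = 1.0, 2.0, 7.5

        def integrand(u):
            return mj.hazard(u, entry, w, tm, lm, b=b)[0]

        expected, err = integrate.quad(integrand, t0, t1, epsabs=0, epsrel=1e-12)
        got = mj.cumulative_hazard(t0, t1, entry, w, tm, lm, b=b)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_consistency_15_vs_61_points(self):
        lm = mj.intercept_slope_submodel(beta=(0.4, 0.12))
        tm = mj.TransitionModel(
            (0, 1), mj.WeibullBaseline(1.3, 0.2),
            association=mj.AssociationStructure("current_value", 0.5),
        )
        h15 = mj.cumulative_hazard(0.5, 9.0, 0.0, [], tm, lm,
                                   rule=gauss_legendre_rule(15))
        h61 = mj.cumulative_hazard(0.5, 9.0, 0.0, [], tm, lm,
                                   rule=gauss_legendre_rule(61))
        assert h15 == pytest.approx(h61, rel=1e-6)

    def test_survival_nonincreasing(self):
        lm = mj.intercept_slope_submodel(beta=(0.4, 0.12))
        tm = mj.TransitionModel(
            (0, 1), mj.WeibullBaseline(0.8, 0.3),
            association=mj.AssociationStructure("current_value", 0.5),
        )
        ts = np.linspace(0.1, 12.0, 25)
        H = [mj.cumulative_hazard(0.0, t, 0.0, [], tm, lm, b=(0.1, 0.02))
             for t in ts]
        assert np.all(np.diff(H) >= 0)

    def test_reversed_interval_rejected(self):
        lm = mj.intercept_slope_submodel(beta=(0.0, 0.0))
        tm = mj.TransitionModel((0, 1), mj.WeibullBaseline(1.0, 0.3))
        with pytest.raises(ValueError, match="t0 <= t1"):
            mj.cumulative_hazard(2.0, 1.0, 0.0, [], tm, lm)


class TestLongitudinalLoglik:
    def test_single_observation_at_mean(self):
        lm = mj.intercept_slope_submodel(beta=(0.5, 0.0), sigma_e2=1.0)
        s = mj.SubjectRecord("a", [1.0], [0.5], [], [(0, 0.0)], 2.0)
        got = mj.longitudinal_loglik(s, [0], lm, b=(0.0, 0.0))
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_empty_index_set(self):
        lm = mj.intercept_slope_submodel(beta=(0.5, 0.0), sigma_e2=1.0)
        s = mj.SubjectRecord("a", [1.0], [0.5], [], [(0, 0.0)], 2.0)
        assert mj.longitudinal_loglik(s, [], lm) == 0.0

    def test_matches_normal_density_sum(self):
        lm = mj.intercept_slope_submodel(beta=(1.0, 0.5), sigma_e2=0.3)
        b = np.array([0.2, -0.1])
        s = mj.SubjectRecord("a", [0.5, 1.0, 2.0], [1.4, 1.1, 2.3], [],
                             [(0, 0.0)], 3.0)
        mu = 1.2 + 0.4 * s.obs_times
        expected = stats.norm.logpdf(s.obs_values, mu, math.sqrt(0.3)).sum()
        got = mj.longitudinal_loglik(s, [0, 1, 2], lm, b=b)
        assert got == pytest.approx(expected, abs=1e-12)


class TestEventLoglik:
    RATES = {(0, 1): 0.1, (0, 2): 0.2, (0, 4): 0.05,
             (1, 3): 0.15, (1, 4): 0.06, (2, 3): 0.12, (2, 4): 0.07,
             (3, 4): 0.2}

    def test_censored_subject_closed_form(self, fig1_graph):
        spec = constant_hazard_spec(fig1_graph, self.RATES)
        s = mj.SubjectRecord("c", [0.0], [0.0], [0.0], [(0, 0.0)], 6.0)
        got = mj.multistate_loglik(s, spec)
        assert got == pytest.approx(-6.0 * (0.1 + 0.2 + 0.05), abs=1e-10)

    def test_one_transition_closed_form(self, fig1_graph, one_subject):
        spec = constant_hazard_spec(fig1_graph, self.RATES)
        got = mj.multistate_loglik(one_subject, spec)
        expected = (
            math.log(0.2) - 4.0 * (0.1 + 0.2 + 0.05)   # sojourn in 0, exit to 2
            + math.log(0.07) - 4.0 * (0.12 + 0.07)     # sojourn in 2, exit to 4
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_transition_weibull_closed_form(self):
        # survival log density: log h(tau) - scale * tau^shape
        g = mj.TransitionGraph([(0, 1)])
        lm = mj.intercept_slope_submodel(beta=(0.0, 0.0), sigma_e2=1.0,
                                         Sigma_b=np.eye(2))
        tm = mj.TransitionModel((0, 1), mj.WeibullBaseline(2.0, 0.5))
        spec = mj.JointModelSpec(g, lm, {(0, 1): tm})
        tau = 1.3
        s = mj.SubjectRecord("e", [0.0], [0.0], [], [(0, 0.0), (1, tau)], tau)
        bd = mj.build_block_dataset([s], mj.single_transition_blocks(g)[0])
        got = mj.single_transition_loglik(bd, 0, spec)
        expected = math.log(2.0 * tau * 0.5) - 0.5 * tau**2
        assert got == pytest.approx(expected, abs=1e-10)

    def test_censored_exposure(self):
        g = mj.TransitionGraph([(0, 1)])
        spec = constant_hazard_spec(g, {(0, 1): 0.4})
        s = mj.SubjectRecord("c", [0.0], [0.0], [0.0], [(0, 0.0)], 3.5)
        bd = mj.build_block_dataset([s], mj.single_transition_blocks(g)[0])
        assert mj.single_transition_loglik(bd, 0, spec) == pytest.approx(
            -0.4 * 3.5, abs=1e-12)


class TestFactorization:
    """Eq-level identity for unidirectional processes: the full multistate
    log-likelihood equals the sum over entered competing-risk blocks, and
    each block equals the sum of its cause-specific survival terms."""

    @pytest.mark.parametrize("seed", [0, 1])
    def test_full_equals_blocks_equals_causes(self, seed):
        cfg = mj.model1_preset(15, seed=seed)
        subjects, latent = mj.simulate_dataset(cfg, seed=seed, return_latent=True)
        spec = cfg.spec
        blocks = mj.competing_risk_blocks(spec.graph)
        datasets = [mj.build_block_dataset(subjects, b, "historical")
                    for b in blocks]
        for i, s in enumerate(subjects):
            b = latent["b"][i]
            full = mj.multistate_loglik(s, spec, b)
            cr_sum = 0.0
            for bd in datasets:
                if s.id not in bd.members:
                    continue
                m = bd.members.index(s.id)
                cr = mj.competing_risk_loglik(bd, m, spec, b)
                st_sum = sum(
                    mj.single_transition_loglik(
                        mj.single_transition_view(bd, k), m, spec, b)
                    for k in bd.block.terminal_states
                )
                assert cr == pytest.approx(st_sum, abs=1e-10)
                cr_sum += cr
            assert full == pytest.approx(cr_sum, abs=1e-10)


class TestEvaluator:
    def test_matches_reference_implementations(self, m1_config, m1_subjects):
        subjects, latent = m1_subjects
        spec = m1_config.spec
        theta = theta_from_spec(spec)
        B = latent["b"]
        ev = JointEvaluator.for_full_data(subjects, spec)
        c = ev.components(theta, B)
        ref_event = [mj.multistate_loglik(s, spec, B[i])
                     for i, s in enumerate(subjects)]
        ref_long = [
            mj.longitudinal_loglik(s, np.arange(s.obs_times.size),
                                   spec.longitudinal, B[i])
            for i, s in enumerate(subjects)
        ]
        np.testing.assert_allclose(c["event"], ref_event, atol=1e-10)
        np.testing.assert_allclose(c["long"], ref_long, atol=1e-10)
        comp = ev.loglik_components(theta, B)
        assert comp.total == pytest.approx(
            float(c["long"].sum() + c["event"].sum()))
        np.testing.assert_allclose(comp.pointwise, c["long"] + c["event"])

    def test_block_evaluator_matches_reference(self, m1_config, m1_subjects):
        subjects, latent = m1_subjects
        spec = m1_config.spec
        theta = theta_from_spec(spec)
        block = mj.competing_risk_blocks(spec.graph)[0]
        bd = mj.build_block_dataset(subjects, block, "concurrent")
        B = np.array([latent["b"][int(m[1:])] for m in bd.members])
        ev = JointEvaluator.for_block(bd, spec)
        c = ev.components(theta, B)
        ref = [mj.competing_risk_loglik(bd, i, spec, B[i]) for i in range(bd.n)]
        np.testing.assert_allclose(c["event"], ref, atol=1e-10)

    def test_partial_update_equals_full(self, m1_config, m1_subjects):
        subjects, latent = m1_subjects
        spec = m1_config.spec
        theta = theta_from_spec(spec)
        ev = JointEvaluator.for_full_data(subjects, spec)
        st = ev.full_state(theta, latent["b"])
        theta2 = {**theta, "trans": dict(theta["trans"])}
        theta2["trans"][(0, 2)] = {**theta["trans"][(0, 2)],
                                   "shape": 1.5, "alpha": np.array([-0.6])}
        st_partial = ev.update_groups(st, theta2, ev.dependent_groups(1))
        st_full = ev.full_state(theta2, latent["b"])
        np.testing.assert_allclose(st_partial["parts"], st_full["parts"],
                                   atol=1e-12)

    def test_zero_association_event_independent_of_b(self, fig1_graph,
                                                     m1_subjects):
        subjects, latent = m1_subjects
        spec = constant_hazard_spec(fig1_graph, TestEventLoglik.RATES)
        theta = theta_from_spec(spec)
        ev = JointEvaluator.for_full_data(subjects, spec)
        c1 = ev.components(theta, np.zeros((len(subjects), 2)))
        rng = np.random.default_rng(3)
        c2 = ev.components(theta, rng.normal(size=(len(subjects), 2)))
        np.testing.assert_allclose(c1["event"], c2["event"], atol=1e-12)
        assert not np.allclose(c1["long"], c2["long"])


class TestPosteriorKernels:
    def test_one_block_graph_cr_equals_msm(self):
        g = mj.TransitionGraph([(0, 1), (0, 2)])
        lm = mj.intercept_slope_submodel(beta=(0.1, 0.05), sigma_e2=0.4,
                                         Sigma_b=np.diag([0.3, 0.01]))
        trans = {
            key: mj.TransitionModel(
                key, mj.WeibullBaseline(1.2, 0.2), gamma=np.empty(0),
                association=mj.AssociationStructure("current_value", 0.3))
            for key in g.transitions
        }
        spec = mj.JointModelSpec(g, lm, trans)
        subs = [
            mj.SubjectRecord("a", [0.0, 1.0], [0.2, 0.4], [],
                             [(0, 0.0), (1, 1.5)], 1.5),
            mj.SubjectRecord("b", [0.0, 2.0], [0.0, 0.1], [],
                             [(0, 0.0)], 3.0),
        ]
        b = np.array([[0.1, 0.0], [-0.2, 0.05]])
        priors = mj.PriorSpec()
        k_msm = mj.log_posterior_kernel("jm-msm", subs, spec, priors, b)
        bd = mj.build_block_dataset(subs, mj.competing_risk_blocks(g)[0],
                                    "historical")
        k_cr = mj.log_posterior_kernel("jm-cr", bd, spec, priors, b)
        assert k_cr == pytest.approx(k_msm, abs=1e-10)

    def test_single_terminal_st_equals_cr(self):
        g = mj.TransitionGraph([(0, 1)])
        spec = constant_hazard_spec(g, {(0, 1): 0.3})
        s = mj.SubjectRecord("a", [0.0, 1.0], [0.1, 0.2], [0.0],
                             [(0, 0.0), (1, 2.0)], 2.0)
        bd = mj.build_block_dataset([s], mj.competing_risk_blocks(g)[0])
        st = mj.single_transition_view(bd, 1)
        b = np.zeros((1, 2))
        priors = mj.PriorSpec()
        assert mj.log_posterior_kernel("jm-st", st, spec, priors, b) == \
            pytest.approx(mj.log_posterior_kernel("jm-cr", bd, spec, priors, b),
                          abs=1e-12)

    def test_unknown_approach_rejected(self):
        g = mj.TransitionGraph([(0, 1)])
        spec = constant_hazard_spec(g, {(0, 1): 0.3})
        with pytest.raises(ValueError, match="unknown approach"):
            mj.log_posterior_kernel("jm-xyz", [], spec, mj.PriorSpec(),
                                    np.zeros((0, 2)))
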