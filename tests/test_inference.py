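import numpy as np
import pytest

import msjoint as mj
from msjoint.inference import ParameterMap, split_rhat

from conftest import constant_hazard_spec


def tiny_config(**kw):
    base = dict(n_draws=60, burn_in=60, chains=1, seed=5)
    base.update(kw)
    return mj.SamplerConfig(**base)


class TestSplitRhat:
    def test_identical_constant_chains(self):
        draws = np.ones((2, 100, 3))
        np.testing.assert_allclose(split_rhat(draws), 1.0)

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(1, 200, 1))
        b = rng.normal(50, 1, size=(1, 200, 1))
        assert split_rhat(np.concatenate([a, b]))[0] > 5

    def test_matches_arviz(self):
        import arviz as az

        rng = np.random.default_rng(1)
        draws = rng.normal(size=(4, 250, 3)) * [1.0, 2.0, 0.5]
        draws[1] += 0.3
        ours = split_rhat(draws)
        theirs = np.array([
            float(az.rhat(az.convert_to_dataset(draws[:, :, j: j + 1]),
                          method="split")["x"].values.ravel()[0])
            for j in range(3)
        ])
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            split_rhat(np.ones((2, 2, 1)))


class TestParameterMap:
    def make(self, priors=None):
        cfg = mj.model1_preset(5, seed=0)
        return ParameterMap(cfg.spec, list(cfg.spec.graph.transitions),
                            priors or mj.PriorSpec())

    def test_round_trip_constrained(self):
        pmap = self.make()
        rng = np.random.default_rng(2)
        z = rng.normal(scale=0.5, size=pmap.n_params)
        theta = pmap.to_theta(z)
        vec = pmap.flatten_constrained(theta)
        theta2 = pmap.theta_from_constrained(vec)
        np.testing.assert_allclose(theta2["beta"], theta["beta"])
        np.testing.assert_allclose(theta2["Sigma_b"], theta["Sigma_b"],
                                   atol=1e-12)
        for key in pmap.trans_keys:
            for k, v in theta["trans"][key].items():
                np.testing.assert_allclose(theta2["trans"][key][k], v)

    def test_sigma_b_valid_covariance(self):
        pmap = self.make()
        rng = np.random.default_rng(3)
        for _ in range(20):
            z = rng.normal(scale=1.5, size=pmap.n_params)
            S = pmap.to_theta(z)["Sigma_b"]
            assert np.all(np.linalg.eigvalsh(S) > 0)

    def test_lkj_prior_matches_r2_closed_form(self):
        """For r=2 the vine-Beta construction must reduce to the LKJ(eta)
        density (1-rho^2)^(eta-1) up to the tanh jacobian and a constant."""
        pmap = self.make()
        zs = np.linspace(-1.2, 1.2, 7)
        vals = []
        for zc in zs:
            z = np.zeros(pmap.n_params)
            ci = pmap.cov_idx[-1]  # the single correlation entry
            z[ci] = zc
            rho = np.tanh(zc)
            lkj = (pmap.priors.lkj_eta - 1.0) * np.log(1 - rho**2)
            jac = np.log(1 - rho**2)
            vals.append(pmap.log_prior(z) - lkj - jac)
        np.testing.assert_allclose(vals, vals[0], atol=1e-10)

    def test_log_prior_finite_at_origin(self):
        pmap = self.make()
        assert np.isfinite(pmap.log_prior(np.zeros(pmap.n_params)))


class TestFitting:
    @pytest.mark.parametrize("burn", [0, 60])
    def test_seed_reproducibility(self, m1_subjects, m1_config, burn):
        subjects, _ = m1_subjects
        f1 = mj.fit_jm_msm(subjects, m1_config.spec,
                           config=tiny_config(burn_in=burn))
        f2 = mj.fit_jm_msm(subjects, m1_config.spec,
                           config=tiny_config(burn_in=burn))
        np.testing.assert_array_equal(f1.draws, f2.draws)
        np.testing.assert_array_equal(f1.b_draws, f2.b_draws)

    def test_jm_cr_block_count_and_independence(self, m1_subjects, m1_config):
        subjects, _ = m1_subjects
        fits1 = mj.fit_jm_cr(subjects, m1_config.spec, strategy="concurrent",
                             config=tiny_config())
        assert len(fits1) == 4
        assert [f.block for f in fits1] == [
            "B0->{1,2,4}", "B1->{3,4}", "B2->{3,4}", "B3->{4}"]
        # re-running yields identical per-block draws (block independence)
        fits2 = mj.fit_jm_cr(subjects, m1_config.spec, strategy="concurrent",
                             config=tiny_config())
        for a, b in zip(fits1, fits2):
            np.testing.assert_array_equal(a.draws, b.draws)

    def test_jm_st_block_count(self, m1_subjects, m1_config):
        subjects, _ = m1_subjects
        fits = mj.fit_jm_st(subjects, m1_config.spec, strategy="historical",
                            config=tiny_config())
        assert len(fits) == 8
        assert all(f.approach == "jm-st" for f in fits)

    def test_one_block_graph_single_fit(self):
        g = mj.TransitionGraph([(0, 1)])
        spec = constant_hazard_spec(g, {(0, 1): 0.3})
        rng = np.random.default_rng(4)
        subs = []
        for i in range(30):
            T = rng.exponential(1 / 0.3)
            C = rng.uniform(2, 5)
            path = [(0, 0.0)] + ([(1, T)] if T < C else [])
            subs.append(mj.SubjectRecord(
                f"x{i}", [0.0, min(T, C) / 2], rng.normal(size=2), [0.0],
                path, max(C, T + 1e-6) if T < C else C))
        fits = mj.fit_jm_cr(subs, spec, config=tiny_config())
        assert len(fits) == 1
        assert fits[0].draws.shape == (1, 60, len(fits[0].param_names))

    def test_posterior_fit_summary_shape(self, m1_subjects, m1_config):
        subjects, _ = m1_subjects
        fit = mj.fit_jm_msm(subjects, m1_config.spec,
                            config=tiny_config(chains=2))
        s = fit.summary()
        assert list(s.columns) == ["mean", "sd", "q2.5", "q50", "q97.5", "rhat"]
        assert fit.n_total_draws == 120
        lo, hi = fit.credible_interval("beta[0]")
        assert lo < hi

    def test_lmm_conditional_matches_mixedlm(self):
        """With no events and no association the longitudinal side is a plain
        LMM: posterior means must agree with the statsmodels MixedLM fit."""
        import statsmodels.api as sm
        import pandas as pd

        cfg = mj.model1_preset(
            150, seed=21,
            overrides={"alpha": {k: 0.0 for k in
                                 mj.five_state_progressive_graph().transitions},
                       "censoring": (13.0, 24.0)})
        subjects, _ = mj.simulate_dataset(cfg, seed=21, return_latent=True)
        fit = mj.fit_jm_msm(subjects, cfg.spec,
                            config=mj.SamplerConfig(n_draws=300, burn_in=400,
                                                    chains=2, seed=6))
        rows = [{"id": s.id, "t": t, "y": y}
                for s in subjects for t, y in zip(s.obs_times, s.obs_values)]
        df = pd.DataFrame(rows)
        ml = sm.MixedLM.from_formula("y ~ t", df, groups="id",
                                     re_formula="~t").fit(reml=False)
        pm = fit.posterior_mean()
        sd = dict(zip(fit.param_names,
                      fit.flat_draws().std(axis=0, ddof=1)))
        assert abs(pm["beta[0]"] - ml.params["Intercept"]) < \
            3 * (sd["beta[0]"] + ml.bse["Intercept"])
        assert abs(pm["beta[1]"] - ml.params["t"]) < \
            3 * (sd["beta[1]"] + ml.bse["t"])
        assert abs(pm["sigma_e2"] - ml.scale) < 4 * sd["sigma_e2"]
        sd_b0_ml = float(np.sqrt(ml.cov_re.iloc[0, 0]))
        assert abs(pm["re_sd[0]"] - sd_b0_ml) < max(0.15, 4 * sd["re_sd[0]"])


class TestEdgeCases:
    def test_random_initialization_runs(self, m1_subjects, m1_config):
        subjects, _ = m1_subjects
        fit = mj.fit_jm_msm(subjects, m1_config.spec,
                            config=tiny_config(init="random"))
        assert np.all(np.isfinite(fit.flat_draws()))

    def test_empty_blocks_skipped_with_warning(self, fig1_graph, caplog):
        # every subject censored in state 0: only the first block has members
        subs = [mj.SubjectRecord(f"c{i}", [0.0, 1.0], [0.1, 0.2], [0.0],
                                 [(0, 0.0)], 5.0) for i in range(12)]
        spec = mj.model1_preset(5, seed=0).spec
        with caplog.at_level("WARNING"):
            fits = mj.fit_jm_cr(subs, spec, config=tiny_config())
        assert len(fits) == 1
        assert fits[0].block.startswith("B0")
        assert sum("empty block" in r.message for r in caplog.records) == 3


@pytest.fixture(scope="module")
def m2_data():
    cfg = mj.model2_preset(40, seed=2)
    return cfg, mj.simulate_dataset(cfg, seed=2)


class TestSplineModelFitting:
    """Ten-transition preset: clock-forward spline baselines with
    proportional anchors and a three-dimensional random-effects vector."""

    def test_all_three_approaches_run(self, m2_data):
        cfg, subs = m2_data
        small = mj.SamplerConfig(n_draws=20, burn_in=20, chains=1, seed=2)
        assert len(mj.fit_jm_cr(subs, cfg.spec, config=small)) == 4
        assert len(mj.fit_jm_st(subs, cfg.spec, config=small)) == 10
        msm = mj.fit_jm_msm(subs, cfg.spec, config=small)
        assert sum(n.startswith("eta[") for n in msm.param_names) == 15
        assert sum(n.startswith("log_ratio[") for n in msm.param_names) == 7

    def test_out_of_block_anchors_promoted(self, m2_data):
        """Fitting the block out of state 1 alone: its proportional
        baselines reference anchors outside the block, so they must be
        promoted to free splines to stay identifiable."""
        cfg, subs = m2_data
        small = mj.SamplerConfig(n_draws=20, burn_in=20, chains=1, seed=2)
        fit = mj.fit_jm_cr(subs, cfg.spec, config=small)[1]
        assert fit.block.startswith("B1")
        free_splines = {n.split("[")[1].rstrip("]") for n in fit.param_names
                        if n.startswith("eta[")}
        assert free_splines == {"1->2", "1->3", "1->4"}


def test_strategy_changes_block_data(m1_subjects, m1_config):
    subjects, _ = m1_subjects
    block = mj.competing_risk_blocks(m1_config.spec.graph)[1]
    hist = mj.build_block_dataset(subjects, block, "historical")
    conc = mj.build_block_dataset(subjects, block, "concurrent")
    n_hist = sum(len(ix) for ix in hist.long_index)
    n_conc = sum(len(ix) for ix in conc.long_index)
    assert n_conc <= n_hist
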