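import math

import numpy as np
import pytest
from scipy import stats

import msjoint as mj
from msjoint.model_spec import (
    default_spline_knots,
    half_cauchy_logpdf,
    model2_nonlinear_submodel,
)


class TestTrajectory:
    def test_intercept_slope_mean(self):
        lm = mj.intercept_slope_submodel(beta=(1.0, 0.5))
        assert mj.mu(2.0, [], lm, b=(0.0, 0.0))[0] == pytest.approx(2.0)
        assert mj.mu(0.0, [], lm, b=(-1.0, -0.5))[0] == pytest.approx(0.0)

    def test_slope_constant_in_time(self):
        lm = mj.intercept_slope_submodel(beta=(1.0, 0.5))
        for t in (0.0, 1.7, 12.0):
            assert mj.dmu_dt(t, [], lm, b=(0.0, 0.1))[0] == pytest.approx(0.6)

    def test_nonlinear_basis_vanishes_at_zero(self):
        # f1(0) = (1+0)^(-1.2) - 1 = 0 and f2(0) = 0: intercept terms only
        lm = model2_nonlinear_submodel(beta=(2.0, 0.3, 1.0, 0.2, 0.05, 0.02))
        w = np.array([0.7])
        got = mj.mu(0.0, w, lm, b=(0.4, 9.0, 9.0))[0]
        assert got == pytest.approx(2.0 + 0.3 * 0.7 + 0.4)

    @pytest.mark.parametrize("t", [0.5, 1.0, 3.3, 10.0])
    def test_nonlinear_slope_matches_finite_differences(self, t):
        lm = model2_nonlinear_submodel(beta=(2.0, 0.3, 1.0, 0.2, 0.05, 0.02))
        w = np.array([-0.4])
        b = np.array([0.1, -0.2, 0.03])
        h = 1e-6
        fd = (mj.mu(t + h, w, lm, b=b)[0] - mj.mu(t - h, w, lm, b=b)[0]) / (2 * h)
        assert mj.dmu_dt(t, w, lm, b=b)[0] == pytest.approx(fd, abs=1e-6)

    def test_missing_derivative_raises(self):
        lm = mj.LongitudinalSubmodel(
            q1=1, r=1,
            fixed_basis=lambda t, w: np.ones((len(t), 1)),
            random_basis=lambda t: np.ones((len(t), 1)),
            beta=np.array([0.0]),
        )
        with pytest.raises(ValueError, match="current-slope"):
            lm.dmu_dt(1.0, [])


class TestHazard:
    @staticmethod
    def _tm(shape, scale, timescale="clock_reset", gamma=(), assoc=None):
        return mj.TransitionModel(
            transition=(0, 1),
            baseline=mj.WeibullBaseline(shape, scale),
            timescale=timescale,
            gamma=np.asarray(gamma, dtype=float),
            association=assoc or mj.AssociationStructure("none"),
        )

    def test_constant_hazard(self):
        lm = mj.intercept_slope_submodel(beta=(0.0, 0.0))
        tm = self._tm(1.0, 0.3)
        for t in (0.1, 2.0, 11.0):
            assert mj.hazard(t, 0.0, [], tm, lm)[0] == pytest.approx(0.3)

    def test_clock_reset_weibull_value(self):
        # shape=2, scale=0.5, entry=4, t=6: h = 2 * (t-4)^1 * 0.5 = 2.0
        lm = mj.intercept_slope_submodel(beta=(0.0, 0.0))
        tm = self._tm(2.0, 0.5)
        assert mj.hazard(6.0, 4.0, [], tm, lm)[0] == pytest.approx(2.0)

    def test_association_and_covariate_multipliers(self):
        lm = mj.intercept_slope_submodel(beta=(0.7, 0.0))
        tm = self._tm(1.0, 0.3, gamma=(0.4,),
                      assoc=mj.AssociationStructure("current_value", 1.0))
        got = mj.hazard(1.0, 0.0, [0.5], tm, lm, b=(0.0, 0.0))[0]
        assert got == pytest.approx(0.3 * math.exp(0.4 * 0.5 + 0.7))

    def test_before_entry_rejected(self):
        lm = mj.intercept_slope_submodel(beta=(0.0, 0.0))
        with pytest.raises(ValueError, match="before state entry"):
            mj.hazard(1.0, 2.0, [], self._tm(1.0, 0.3), lm)

    def test_clock_equivalence_at_zero_entry(self):
        lm = mj.intercept_slope_submodel(beta=(0.3, 0.1))
        assoc = mj.AssociationStructure("current_value", 0.5)
        fw = self._tm(1.4, 0.2, "clock_forward", assoc=assoc)
        rs = self._tm(1.4, 0.2, "clock_reset", assoc=assoc)
        t = np.array([0.5, 1.0, 7.0])
        np.testing.assert_allclose(
            mj.hazard(t, 0.0, [], fw, lm, b=(0.1, 0.0)),
            mj.hazard(t, 0.0, [], rs, lm, b=(0.1, 0.0)),
        )

    @pytest.mark.parametrize("kind,alpha,expected_log", [
        ("none", (), 0.0),
        ("current_value", (0.5,), 0.5 * 1.1),
        ("current_slope", (2.0,), 2.0 * 0.1),
        ("shared_random_effects", (1.0, -1.0), 0.6 + 0.1),
        ("current_value_quadratic", (0.5, 0.25), 0.5 * 1.1 + 0.25 * 1.1**2),
    ])
    def test_association_kinds(self, kind, alpha, expected_log):
        lm = mj.intercept_slope_submodel(beta=(0.3, 0.2))
        b = np.array([0.6, -0.1])  # mu(2) = 0.3+0.6 + (0.2-0.1)*2 = 1.1
        assoc = mj.AssociationStructure(kind, np.asarray(alpha, dtype=float))
        tm = self._tm(1.0, 1.0, assoc=assoc)
        got = mj.hazard(2.0, 0.0, [], tm, lm, b=b)[0]
        if kind == "shared_random_effects":
            expected_log = float(np.array([1.0, -1.0]) @ b)
        assert math.log(got) == pytest.approx(expected_log)

    def test_association_arity_enforced(self):
        with pytest.raises(ValueError, match="parameter"):
            mj.AssociationStructure("current_value_quadratic", 0.5).validate_arity(2)
        with pytest.raises(ValueError, match="covariate_index"):
            mj.AssociationStructure("current_value_by_covariate", (0.5, 0.1))


class TestSplineBaseline:
    def test_log_hazard_continuity_at_interior_knot(self):
        knots = default_spline_knots(16.0, interior=(8.0,))
        bl = mj.BSplineLogBaseline(coefs=[0.1, -0.4, 0.3, 0.2, -0.1], knots=knots)
        eps = 1e-7
        lo, hi = bl.log_h0(8.0 - eps)[0], bl.log_h0(8.0 + eps)[0]
        assert lo == pytest.approx(hi, abs=1e-5)

    def test_partition_of_unity_shift(self):
        # adding c to every coefficient shifts log h0 by exactly c
        knots = default_spline_knots(16.0, interior=(8.0,))
        c = np.array([0.1, -0.4, 0.3, 0.2, -0.1])
        a = mj.BSplineLogBaseline(coefs=c, knots=knots)
        b = mj.BSplineLogBaseline(coefs=c + 0.7, knots=knots)
        t = np.linspace(0.0, 16.0, 33)
        np.testing.assert_allclose(b.log_h0(t), a.log_h0(t) + 0.7, atol=1e-12)

    def test_coefficient_count_validated(self):
        knots = default_spline_knots(16.0)
        with pytest.raises(ValueError, match="coefficients"):
            mj.BSplineLogBaseline(coefs=np.zeros(7), knots=knots)


class TestPriors:
    def make_spec(self, **kw):
        lm = mj.intercept_slope_submodel(
            beta=kw.get("beta", (0.0, 0.0)),
            sigma_e2=kw.get("sigma_e2", 1.0),
            Sigma_b=kw.get("Sigma_b", np.eye(2)),
        )
        g = mj.TransitionGraph([(0, 1)])
        tm = mj.TransitionModel(
            (0, 1), mj.WeibullBaseline(*kw.get("weibull", (1.0, 1.0))),
            gamma=np.empty(0),
            association=mj.AssociationStructure(
                "current_value", kw.get("alpha", 0.0)),
        )
        return mj.JointModelSpec(g, lm, {(0, 1): tm})

    def test_normal_mode_density(self):
        # alpha=0 under N(0, 100^2) contributes -log(100 sqrt(2 pi))
        base = mj.log_prior(self.make_spec(), mj.PriorSpec())
        shifted = mj.log_prior(self.make_spec(alpha=100.0), mj.PriorSpec())
        assert base - shifted == pytest.approx(0.5)  # half a prior sd

    def test_out_of_support_is_minus_inf(self):
        assert half_cauchy_logpdf(-1.0, 1.0) == -np.inf
        spec = self.make_spec(sigma_e2=1.0)
        spec.longitudinal.sigma_e2 = -1.0
        assert mj.log_prior(spec, mj.PriorSpec()) == -np.inf

    def test_inverse_gamma_matches_density_formula(self):
        a, b = 0.01, 0.01
        x = 1.0
        expected = a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(x) - b / x
        assert stats.invgamma.logpdf(x, a, scale=b) == pytest.approx(
            expected, abs=1e-12)
        p1 = mj.log_prior(self.make_spec(sigma_e2=1.0), mj.PriorSpec())
        p2 = mj.log_prior(self.make_spec(sigma_e2=2.0), mj.PriorSpec())
        d_expected = (stats.invgamma.logpdf(1.0, a, scale=b)
                      - stats.invgamma.logpdf(2.0, a, scale=b))
        assert p1 - p2 == pytest.approx(d_expected, abs=1e-12)

    def test_half_cauchy_density(self):
        x = np.array([0.5, 1.0, 3.0])
        expected = stats.halfcauchy.logpdf(x, scale=2.5)
        np.testing.assert_allclose(half_cauchy_logpdf(x, 2.5), expected, atol=1e-12)


def test_weibull_standard_scale_conversion():
    # h(u) = shape*u^(shape-1)*scale must equal the textbook (k/s)(u/s)^(k-1)
    shape, scale = 1.7, 0.04
    s = mj.weibull_standard_scale(shape, scale)
    u = np.array([0.5, 2.0, 9.0])
    textbook = (shape / s) * (u / s) ** (shape - 1.0)
    ours = np.exp(mj.WeibullBaseline(shape, scale).log_h0(u))
    np.testing.assert_allclose(ours, textbook, rtol=1e-12)


def test_timescale_must_be_uniform():
    lm = mj.intercept_slope_submodel(beta=(0.0, 0.0), sigma_e2=1.0,
                                     Sigma_b=np.eye(2))
    g = mj.TransitionGraph([(0, 1), (0, 2)])
    trans = {
        (0, 1): mj.TransitionModel((0, 1), mj.WeibullBaseline(1, 1),
                                   timescale="clock_reset"),
        (0, 2): mj.TransitionModel((0, 2), mj.WeibullBaseline(1, 1),
                                   timescale="clock_forward"),
    }
    with pytest.raises(ValueError, match="uniform"):
        mj.JointModelSpec(g, lm, trans)
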