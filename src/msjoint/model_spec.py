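"""Model specification: longitudinal submodel, transition hazards, priors.

The joint model links a Gaussian linear mixed model for the biomarker,

    y_ij | b_i ~ N( mu_i(t_ij) , sigma_e^2 ),
    mu_i(t) = X_i(t)' beta + Z_i(t)' b_i,      b_i ~ N(0, Sigma_b),

to cause-specific transition intensities of a unidirectional multistate
process,

    h_jk(t) = h0_jk(B(t)) * exp( w_i' gamma_jk + f(beta, b_i, t, alpha_jk) ),

where ``B(t)`` is study time (clock-forward, Markov) or time since entry to
the current state (clock-reset, semi-Markov), ``h0_jk`` is a Weibull or
log-B-spline baseline, and ``f`` is the association structure sharing the
biomarker's latent trajectory with the hazard.

The Weibull baseline uses the parameterisation h0(u) = delta * u^(delta-1) *
lambda, i.e. the scale multiplies outside rather than entering as
lambda^delta; :func:`weibull_standard_scale` converts to the textbook scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .state_graph import TransitionGraph, validate_graph

__all__ = [
    "LongitudinalSubmodel",
    "intercept_slope_submodel",
    "model2_nonlinear_submodel",
    "WeibullBaseline",
    "BSplineLogBaseline",
    "ProportionalBaseline",
    "weibull_standard_scale",
    "default_spline_knots",
    "AssociationStructure",
    "TransitionModel",
    "JointModelSpec",
    "PriorSpec",
    "mu",
    "dmu_dt",
    "hazard",
    "log_prior",
    "half_cauchy_logpdf",
]


# --------------------------------------------------------------------------
# longitudinal submodel
# --------------------------------------------------------------------------

@dataclass
class LongitudinalSubmodel:
    """Gaussian LMM with user-supplied fixed/random design bases.

    ``fixed_basis(t, w)`` maps a time vector (m,) and covariate vector (q2,)
    to the (m, q1) fixed-effects design; ``random_basis(t)`` to the (m, r)
    random-effects design.  Derivative bases enable the current-slope
    association; they may be None for non-differentiable custom bases.
    Parameter values (beta, sigma_e2, Sigma_b) are carried for simulation
    and initialisation; inference treats them as unknowns.
    """

    q1: int
    r: int
    fixed_basis: Callable[[np.ndarray, np.ndarray], np.ndarray]
    random_basis: Callable[[np.ndarray], np.ndarray]
    fixed_basis_deriv: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    random_basis_deriv: Callable[[np.ndarray], np.ndarray] | None = None
    beta: np.ndarray | None = None
    sigma_e2: float | None = None
    Sigma_b: np.ndarray | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (self.q1,):
                raise ValueError("beta length does not match q1")
        if self.Sigma_b is not None:
            self.Sigma_b = np.asarray(self.Sigma_b, dtype=float)
            if self.Sigma_b.shape != (self.r, self.r):
                raise ValueError("Sigma_b shape does not match r")
            if not np.allclose(self.Sigma_b, self.Sigma_b.T):
                raise ValueError("Sigma_b must be symmetric")
            if np.any(np.linalg.eigvalsh(self.Sigma_b) <= 0):
                raise ValueError("Sigma_b must be positive definite")
        # sigma_e2 = 0 is allowed for noise-free simulation; the likelihood
        # layer rejects non-positive values itself
        if self.sigma_e2 is not None and self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be nonnegative")

    def mu(self, t, w, beta=None, b=None) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        beta = self.beta if beta is None else np.asarray(beta, dtype=float)
        b = np.zeros(self.r) if b is None else np.asarray(b, dtype=float)
        X = self.fixed_basis(t, np.asarray(w, dtype=float))
        Z = self.random_basis(t)
        return X @ beta + Z @ b

    def dmu_dt(self, t, w, beta=None, b=None) -> np.ndarray:
        if self.fixed_basis_deriv is None or self.random_basis_deriv is None:
            raise ValueError(
                f"longitudinal basis {self.name!r} has no derivative; "
                "current-slope association unsupported"
            )
        t = np.atleast_1d(np.asarray(t, dtype=float))
        beta = self.beta if beta is None else np.asarray(beta, dtype=float)
        b = np.zeros(self.r) if b is None else np.asarray(b, dtype=float)
        dX = self.fixed_basis_deriv(t, np.asarray(w, dtype=float))
        dZ = self.random_basis_deriv(t)
        return dX @ beta + dZ @ b


def intercept_slope_submodel(beta=None, sigma_e2=None, Sigma_b=None) -> LongitudinalSubmodel:
    """Random-intercept random-slope LMM: mu_i(t) = (b1+beta1) + (b2+beta2) t."""

    def X(t, w):
        return np.column_stack([np.ones_like(t), t])

    def dX(t, w):
        return np.column_stack([np.zeros_like(t), np.ones_like(t)])

    return LongitudinalSubmodel(
        q1=2, r=2,
        fixed_basis=X, random_basis=lambda t: X(t, None),
        fixed_basis_deriv=dX, random_basis_deriv=lambda t: dX(t, None),
        beta=beta, sigma_e2=sigma_e2, Sigma_b=Sigma_b,
        name="intercept-slope",
    )


def _f1(t):  # nonlinear early-response time basis
    return (1.0 + t) ** (-1.2) - 1.0


def _df1(t):
    return -1.2 * (1.0 + t) ** (-2.2)


def model2_nonlinear_submodel(beta=None, sigma_e2=None, Sigma_b=None) -> LongitudinalSubmodel:
    """Nonlinear-trend LMM with bases (1, f1(t), t), f1(t) = (1+t)^(-1.2) - 1.

    Fixed effects interact a scalar baseline covariate w with each time
    basis: columns (1, w, f1, w*f1, t, w*t), q1 = 6; random effects are an
    intercept plus loadings on f1 and t, r = 3.
    """

    def X(t, w):
        w1 = float(np.atleast_1d(w)[0]) if np.size(w) else 0.0
        one = np.ones_like(t)
        return np.column_stack([one, w1 * one, _f1(t), w1 * _f1(t), t, w1 * t])

    def dX(t, w):
        w1 = float(np.atleast_1d(w)[0]) if np.size(w) else 0.0
        zero = np.zeros_like(t)
        one = np.ones_like(t)
        return np.column_stack([zero, zero, _df1(t), w1 * _df1(t), one, w1 * one])

    def Z(t):
        return np.column_stack([np.ones_like(t), _f1(t), t])

    def dZ(t):
        return np.column_stack([np.zeros_like(t), _df1(t), np.ones_like(t)])

    return LongitudinalSubmodel(
        q1=6, r=3,
        fixed_basis=X, random_basis=Z,
        fixed_basis_deriv=dX, random_basis_deriv=dZ,
        beta=beta, sigma_e2=sigma_e2, Sigma_b=Sigma_b,
        name="model2-nonlinear",
    )


# --------------------------------------------------------------------------
# baseline hazards
# --------------------------------------------------------------------------

@dataclass
class WeibullBaseline:
    """h0(u) = shape * u^(shape-1) * scale, both parameters > 0."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be strictly positive")

    def log_h0(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        with np.errstate(divide="ignore"):
            return math.log(self.shape) + (self.shape - 1.0) * np.log(u) + math.log(self.scale)

    def cumulative(self, u) -> np.ndarray:
        """Closed-form integral of h0 from 0 to u: scale * u^shape."""
        return self.scale * np.asarray(u, dtype=float) ** self.shape

    @property
    def n_params(self) -> int:
        return 2


def weibull_standard_scale(shape: float, scale: float) -> float:
    """Convert to the textbook Weibull scale sigma with h(u)=(k/s)(u/s)^(k-1)."""
    return scale ** (-1.0 / shape)


def default_spline_knots(max_time: float, interior: Sequence[float] = (),
                         degree: int = 3) -> np.ndarray:
    """Clamped knot vector on [0, max_time] with the given interior knots."""
    interior = np.asarray(sorted(interior), dtype=float)
    return np.concatenate([
        np.zeros(degree + 1), interior, np.full(degree + 1, float(max_time)),
    ])


@dataclass
class BSplineLogBaseline:
    """log h0(t) = sum_l eta_l B_l(t) with cubic B-spline bases B_l.

    Evaluation outside the boundary knots clamps t to the boundary, keeping
    the log-hazard constant beyond the observation window.
    """

    coefs: np.ndarray
    knots: np.ndarray
    degree: int = 3

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        self.knots = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knot sequence must be nondecreasing")
        expected = len(self.knots) - self.degree - 1
        if len(self.coefs) != expected:
            raise ValueError(f"need {expected} coefficients for this knot sequence")

    def basis_matrix(self, u) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        uc = np.clip(u, lo, hi - 1e-12 * max(1.0, abs(hi)))
        return BSpline.design_matrix(uc, self.knots, self.degree).toarray()

    def log_h0(self, u) -> np.ndarray:
        return self.basis_matrix(u) @ self.coefs

    @property
    def n_params(self) -> int:
        return len(self.coefs)


@dataclass
class ProportionalBaseline:
    """Baseline proportional to an anchor transition's: h0 = exp(log_ratio) * h0_anchor."""

    anchor: tuple[int, int]
    log_ratio: float = 0.0

    @property
    def n_params(self) -> int:
        return 1


# --------------------------------------------------------------------------
# association structures
# --------------------------------------------------------------------------

_ASSOC_KINDS = (
    "none",
    "current_value",
    "current_slope",
    "shared_random_effects",
    "current_value_quadratic",
    "current_value_by_covariate",
)


@dataclass
class AssociationStructure:
    """How the latent biomarker trajectory enters the log-hazard.

    kinds: ``none`` (0), ``current_value`` (alpha*mu), ``current_slope``
    (alpha*mu'), ``shared_random_effects`` (alpha'b), ``current_value_quadratic``
    (a1*mu + a2*mu^2) and ``current_value_by_covariate``
    (a1*mu + a2*(w_c * mu), with w_c the covariate at ``covariate_index``).
    """

    kind: str
    alpha: np.ndarray | float = 0.0
    covariate_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _ASSOC_KINDS:
            raise ValueError(f"unknown association kind {self.kind!r}")
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.kind == "current_value_by_covariate" and self.covariate_index is None:
            raise ValueError("current_value_by_covariate needs covariate_index")

    def arity(self, r: int) -> int:
        return {
            "none": 0,
            "current_value": 1,
            "current_slope": 1,
            "shared_random_effects": r,
            "current_value_quadratic": 2,
            "current_value_by_covariate": 2,
        }[self.kind]

    def validate_arity(self, r: int) -> None:
        need = self.arity(r)
        if need and self.alpha.size != need:
            raise ValueError(
                f"association {self.kind!r} needs {need} parameter(s), got {self.alpha.size}"
            )

    @property
    def needs_slope(self) -> bool:
        return self.kind == "current_slope"

    def term(self, alpha, mu_vals, dmu_vals, b_rows, w_cov) -> np.ndarray:
        """Vectorised association term f over node rows."""
        alpha = np.atleast_1d(alpha)
        if self.kind == "none":
            return np.zeros(np.shape(mu_vals))
        if self.kind == "current_value":
            return alpha[0] * mu_vals
        if self.kind == "current_slope":
            return alpha[0] * dmu_vals
        if self.kind == "shared_random_effects":
            return b_rows @ alpha
        if self.kind == "current_value_quadratic":
            return alpha[0] * mu_vals + alpha[1] * mu_vals**2
        return alpha[0] * mu_vals + alpha[1] * (w_cov * mu_vals)


# --------------------------------------------------------------------------
# transition models and the joint spec
# --------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Hazard model for one permitted transition j -> k."""

    transition: tuple[int, int]
    baseline: WeibullBaseline | BSplineLogBaseline | ProportionalBaseline
    timescale: str = "clock_reset"
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    association: AssociationStructure = field(
        default_factory=lambda: AssociationStructure("none")
    )

    def __post_init__(self) -> None:
        self.transition = (int(self.transition[0]), int(self.transition[1]))
        if self.timescale not in ("clock_forward", "clock_reset"):
            raise ValueError(f"unknown timescale {self.timescale!r}")
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))


@dataclass
class JointModelSpec:
    """Graph + longitudinal submodel + per-transition hazard models."""

    graph: TransitionGraph
    longitudinal: LongitudinalSubmodel
    transitions: dict[tuple[int, int], TransitionModel]

    def __post_init__(self) -> None:
        validate_graph(self.graph)
        missing = set(self.graph.transitions) - set(self.transitions)
        if missing:
            raise ValueError(f"transitions without a model: {sorted(missing)}")
        scales = {tm.timescale for tm in self.transitions.values()}
        if len(scales) > 1:
            raise ValueError("timescale must be uniform across transitions")
        for tm in self.transitions.values():
            tm.association.validate_arity(self.longitudinal.r)
            if isinstance(tm.baseline, ProportionalBaseline):
                anchor = self.transitions.get(tm.baseline.anchor)
                if anchor is None or isinstance(anchor.baseline, ProportionalBaseline):
                    raise ValueError(
                        f"transition {tm.transition}: anchor {tm.baseline.anchor} "
                        "must be a concrete baseline"
                    )

    @property
    def timescale(self) -> str:
        return next(iter(self.transitions.values())).timescale

    def resolved_baseline(self, trans: tuple[int, int]):
        """(concrete baseline, additive log offset) for a transition."""
        tm = self.transitions[trans]
        if isinstance(tm.baseline, ProportionalBaseline):
            anchor = self.transitions[tm.baseline.anchor]
            return anchor.baseline, tm.baseline.log_ratio
        return tm.baseline, 0.0

    def subset(self, transitions: Sequence[tuple[int, int]],
               graph: TransitionGraph | None = None) -> "JointModelSpec":
        """Restrict to a block's transitions (anchors pulled in as needed)."""
        keys = set(transitions)
        for t in transitions:
            tm = self.transitions[t]
            if isinstance(tm.baseline, ProportionalBaseline):
                keys.add(tm.baseline.anchor)
        sub_graph = graph if graph is not None else TransitionGraph(sorted(keys))
        return JointModelSpec(
            graph=sub_graph,
            longitudinal=self.longitudinal,
            transitions={t: self.transitions[t] for t in sorted(keys)},
        )


# --------------------------------------------------------------------------
# module-level evaluation ops
# --------------------------------------------------------------------------

def mu(t, w, long_model: LongitudinalSubmodel, beta=None, b=None):
    """Latent biomarker mean X(t)'beta + Z(t)'b."""
    return long_model.mu(t, w, beta, b)


def dmu_dt(t, w, long_model: LongitudinalSubmodel, beta=None, b=None):
    """Time derivative of the latent biomarker mean."""
    return long_model.dmu_dt(t, w, beta, b)


def hazard(
    t,
    state_entry_time: float,
    w,
    trans_model: TransitionModel,
    long_model: LongitudinalSubmodel,
    b=None,
    beta=None,
    spec: JointModelSpec | None = None,
) -> np.ndarray:
    """Transition intensity h_jk(t) at study time(s) t.

    The baseline is evaluated at B(t) = t - state_entry_time for clock-reset
    models and at t for clock-forward models.  Proportional baselines need
    ``spec`` to resolve their anchor.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < state_entry_time - 1e-12):
        raise ValueError("hazard requested before state entry time")
    if trans_model.timescale == "clock_reset":
        u = t - state_entry_time
    else:
        u = t
    baseline, offset = trans_model.baseline, 0.0
    if isinstance(baseline, ProportionalBaseline):
        if spec is None:
            raise ValueError("proportional baseline requires the joint spec")
        baseline, offset = spec.resolved_baseline(trans_model.transition)
    log_h0 = baseline.log_h0(u) + offset
    assoc = trans_model.association
    mu_vals = dmu_vals = None
    if assoc.kind in ("current_value", "current_value_quadratic",
                      "current_value_by_covariate"):
        mu_vals = long_model.mu(t, w, beta, b)
    if assoc.needs_slope:
        dmu_vals = long_model.dmu_dt(t, w, beta, b)
    b_arr = np.zeros(long_model.r) if b is None else np.asarray(b, dtype=float)
    b_rows = np.broadcast_to(b_arr, (t.size, long_model.r))
    w_arr = np.atleast_1d(np.asarray(w, dtype=float))
    w_cov = (
        np.full(t.size, w_arr[assoc.covariate_index])
        if assoc.covariate_index is not None and w_arr.size
        else np.zeros(t.size)
    )
    f = assoc.term(assoc.alpha, mu_vals, dmu_vals, b_rows, w_cov)
    lin = float(w_arr @ trans_model.gamma) if trans_model.gamma.size else 0.0
    return np.exp(log_h0 + lin + f)


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

def half_cauchy_logpdf(x, scale: float):
    """log density of |Cauchy(0, scale)|; -inf outside (0, inf)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2),
        -np.inf,
    )
    return out if out.ndim else float(out)


@dataclass
class PriorSpec:
    """Weakly informative independent priors for all model parameters.

    Defaults: N(0, 100^2) for regression-type coefficients (beta, gamma,
    alpha), N(0, 10^2) for spline coefficients and log proportionality
    constants, half-Cauchy(0, 1) for Weibull shape and scale,
    Inv-Gamma(0.01, 0.01) for sigma_e^2, half-Cauchy(0, 2.5) for
    random-effect standard deviations and LKJ(2) for their correlation
    matrix.  ``corr_beta`` switches the r=2 correlation prior to
    (rho+1)/2 ~ Beta(a, a) when set.
    """

    coef_sd: float = 100.0
    eta_sd: float = 10.0
    weibull_hc_scale: float = 1.0
    sigma_e2_ig: tuple[float, float] = (0.01, 0.01)
    re_sd_hc_scale: float = 2.5
    lkj_eta: float = 2.0
    corr_beta: float | None = None

    def normal_logpdf(self, x, sd):
        x = np.asarray(x, dtype=float)
        return -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * (x / sd) ** 2

    def corr_logprior(self, R: np.ndarray) -> float:
        R = np.asarray(R, dtype=float)
        r = R.shape[0]
        if r == 1:
            return 0.0
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0:
            return -np.inf
        if self.corr_beta is not None and r == 2:
            a = self.corr_beta
            return float(stats.beta.logpdf((R[0, 1] + 1) / 2, a, a) - math.log(2.0))
        return (self.lkj_eta - 1.0) * logdet  # unnormalised LKJ kernel


def log_prior(spec: JointModelSpec, priors: PriorSpec) -> float:
    """Sum of independent log prior densities at the spec's parameter values.

    Regression coefficients and the error variance use fully normalised
    densities; the LKJ correlation term is the standard unnormalised kernel
    (eta-1)*log det R.  Out-of-support values yield -inf.
    """
    lm = spec.longitudinal
    if lm.beta is None or lm.sigma_e2 is None or lm.Sigma_b is None:
        raise ValueError("log_prior requires parameter values on the spec")
    total = float(np.sum(priors.normal_logpdf(lm.beta, priors.coef_sd)))
    a, bscale = priors.sigma_e2_ig
    if lm.sigma_e2 <= 0:
        return -np.inf
    total += float(stats.invgamma.logpdf(lm.sigma_e2, a, scale=bscale))
    sds = np.sqrt(np.diag(lm.Sigma_b))
    total += float(np.sum(half_cauchy_logpdf(sds, priors.re_sd_hc_scale)))
    R = lm.Sigma_b / np.outer(sds, sds)
    total += priors.corr_logprior(R)
    for tm in spec.transitions.values():
        bl = tm.baseline
        if isinstance(bl, WeibullBaseline):
            total += float(half_cauchy_logpdf(bl.shape, priors.weibull_hc_scale))
            total += float(half_cauchy_logpdf(bl.scale, priors.weibull_hc_scale))
        elif isinstance(bl, BSplineLogBaseline):
            total += float(np.sum(priors.normal_logpdf(bl.coefs, priors.eta_sd)))
        else:
            total += float(priors.normal_logpdf(bl.log_ratio, priors.eta_sd))
        if tm.gamma.size:
            total += float(np.sum(priors.normal_logpdf(tm.gamma, priors.coef_sd)))
        if tm.association.alpha.size and tm.association.kind != "none":
            need = tm.association.arity(lm.r)
            total += float(np.sum(
                priors.normal_logpdf(tm.association.alpha[:need], priors.coef_sd)
            ))
    if not np.isfinite(total):
        return -np.inf
    return total
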