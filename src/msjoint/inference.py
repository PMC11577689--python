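"""Posterior sampling for the three inference strategies.

``fit_jm_msm`` samples the full joint posterior of all transition parameters,
longitudinal parameters and per-subject random effects.  ``fit_jm_cr`` and
``fit_jm_st`` run the same machinery independently per competing-risk block
or per permitted transition, each conditioning only on that block's data;
blocks can be dispatched in parallel and their wall-times are reported so
that the blockwise cost is the maximum over blocks.

The shipped backend is an adaptive Metropolis-within-Gibbs sampler on the
unconstrained parameter scale: blocked adaptive random-walk updates for the
model parameters (one block for the longitudinal parameters, one per
transition) alternate with vectorised per-subject random-walk updates of the
random effects, whose full conditionals are independent across subjects.
Positive parameters are log-transformed; the random-effects covariance is
parameterised by log standard deviations and canonical partial correlations,
on which the LKJ prior has an exact independent-Beta representation.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .data_model import SubjectRecord, build_block_dataset
from .likelihood import JointEvaluator, gauss_legendre_rule
from .model_spec import (
    BSplineLogBaseline,
    JointModelSpec,
    PriorSpec,
    ProportionalBaseline,
    TransitionModel,
    WeibullBaseline,
)
from .state_graph import competing_risk_blocks

__all__ = [
    "SamplerConfig",
    "PosteriorFit",
    "ParameterMap",
    "fit_jm_msm",
    "fit_jm_cr",
    "fit_jm_st",
    "split_rhat",
]

logger = logging.getLogger(__name__)
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class SamplerConfig:
    """MCMC settings.  ``n_draws`` are kept per chain after ``burn_in``."""

    n_draws: int = 1000
    burn_in: int = 300
    chains: int = 2
    seed: int = 0
    init: str = "zeros"  # or "random"
    thin: int = 1
    quad_points: int = 15
    backend: str = "amwg"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.init not in ("zeros", "random"):
            raise ValueError("init must be 'zeros' or 'random'")


# --------------------------------------------------------------------------
# unconstrained parameterisation
# --------------------------------------------------------------------------

def _cpc_to_chol(cpc: np.ndarray, r: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial corrs."""
    L = np.zeros((r, r))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, r):
        rem = 1.0
        for j in range(i):
            p = cpc[idx]
            idx += 1
            L[i, j] = p * math.sqrt(rem)
            rem *= 1.0 - p * p
        L[i, i] = math.sqrt(max(rem, 1e-300))
    return L


class ParameterMap:
    """Bijection between the unconstrained sampling vector and model parameters.

    Also evaluates the log prior density (with transform Jacobians) on the
    unconstrained scale, and exposes the update-block structure used by the
    sampler: one block of longitudinal parameters followed by one block per
    transition.
    """

    def __init__(
        self,
        spec: JointModelSpec,
        trans_keys: Sequence[tuple[int, int]],
        priors: PriorSpec,
    ) -> None:
        self.spec = spec
        self.priors = priors
        self.trans_keys = list(trans_keys)
        lm = spec.longitudinal
        self.q1, self.r = lm.q1, lm.r
        self.n_corr = self.r * (self.r - 1) // 2
        names: list[str] = [f"beta[{i}]" for i in range(self.q1)]
        names.append("sigma_e2")
        names += [f"re_sd[{i}]" for i in range(self.r)]
        names += [f"re_corr[{i}]" for i in range(self.n_corr)]
        self._long_size = len(names)
        self._trans_slices: dict[tuple[int, int], slice] = {}
        self._trans_layout: dict[tuple[int, int], dict] = {}
        pos = len(names)
        for key in self.trans_keys:
            tm = spec.transitions[key]
            tag = f"{key[0]}->{key[1]}"
            layout = {}
            start = pos
            bl = tm.baseline
            if isinstance(bl, WeibullBaseline):
                layout["family"] = "weibull"
                names += [f"shape[{tag}]", f"scale[{tag}]"]
                pos += 2
            elif isinstance(bl, BSplineLogBaseline):
                layout["family"] = "bspline"
                layout["n_eta"] = bl.n_params
                names += [f"eta[{tag}][{l}]" for l in range(bl.n_params)]
                pos += bl.n_params
            else:
                layout["family"] = "proportional"
                names += [f"log_ratio[{tag}]"]
                pos += 1
            layout["n_gamma"] = tm.gamma.size
            names += [f"gamma[{tag}][{i}]" for i in range(tm.gamma.size)]
            pos += tm.gamma.size
            layout["n_alpha"] = tm.association.arity(self.r)
            names += [f"alpha[{tag}][{i}]" for i in range(layout["n_alpha"])]
            pos += layout["n_alpha"]
            self._trans_slices[key] = slice(start, pos)
            self._trans_layout[key] = layout
        self.names = names
        self.n_params = pos
        self.alpha_idx = np.array(
            [i for i, nm in enumerate(names) if nm.startswith("alpha[")],
            dtype=int)
        # vine-Beta shape per CPC entry (row-major over the lower triangle)
        shapes = []
        for i in range(1, self.r):
            for j in range(i):
                if priors.corr_beta is not None and self.r == 2:
                    shapes.append(priors.corr_beta)
                else:
                    shapes.append(priors.lkj_eta + (self.r - 2 - j) / 2.0)
        self._cpc_shapes = np.asarray(shapes)

    # ---- blocks ----------------------------------------------------------

    def blocks(self) -> list[np.ndarray]:
        out = [np.arange(self._long_size)]
        for key in self.trans_keys:
            sl = self._trans_slices[key]
            out.append(np.arange(sl.start, sl.stop))
        return out

    def trans_blocks(self) -> list[np.ndarray]:
        """Unconstrained index block per transition, in trans_keys order."""
        return self.blocks()[1:]

    @property
    def beta_idx(self) -> np.ndarray:
        return np.arange(self.q1)

    @property
    def sigma_pos(self) -> int:
        return self.q1

    @property
    def cov_idx(self) -> np.ndarray:
        """Indices of the random-effects log-sds and correlation z-values."""
        return np.arange(self.q1 + 1, self._long_size)

    # ---- transforms ------------------------------------------------------

    def to_theta(self, z: np.ndarray) -> dict:
        z = np.asarray(z, dtype=float)
        q1, r = self.q1, self.r
        beta = z[:q1]
        sigma_e2 = math.exp(z[q1])
        sds = np.exp(z[q1 + 1: q1 + 1 + r])
        cpc = np.tanh(z[q1 + 1 + r: q1 + 1 + r + self.n_corr])
        Lc = _cpc_to_chol(cpc, r)
        Lb = Lc * sds[:, None]
        Sigma_b = Lb @ Lb.T
        theta = {"beta": beta, "sigma_e2": sigma_e2, "Sigma_b": Sigma_b,
                 "re_sd": sds, "corr_chol": Lc, "trans": {}}
        for key in self.trans_keys:
            sl = self._trans_slices[key]
            lay = self._trans_layout[key]
            v = z[sl]
            pos = 0
            p: dict = {}
            if lay["family"] == "weibull":
                p["shape"] = math.exp(v[0])
                p["scale"] = math.exp(v[1])
                pos = 2
            elif lay["family"] == "bspline":
                p["eta"] = v[:lay["n_eta"]].copy()
                pos = lay["n_eta"]
            else:
                p["log_ratio"] = float(v[0])
                pos = 1
            p["gamma"] = v[pos:pos + lay["n_gamma"]].copy()
            pos += lay["n_gamma"]
            p["alpha"] = v[pos:pos + lay["n_alpha"]].copy()
            theta["trans"][key] = p
        return theta

    def log_prior(self, z: np.ndarray) -> float:
        """Log prior density of the induced parameters + transform Jacobians."""
        pr = self.priors
        q1, r = self.q1, self.r
        z = np.asarray(z, dtype=float)
        total = float(np.sum(pr.normal_logpdf(z[:q1], pr.coef_sd)))
        a, bsc = pr.sigma_e2_ig
        s2 = math.exp(z[q1])
        total += float(stats.invgamma.logpdf(s2, a, scale=bsc)) + z[q1]
        zsd = z[q1 + 1: q1 + 1 + r]
        sds = np.exp(zsd)
        total += float(np.sum(
            np.log(2.0 / (math.pi * pr.re_sd_hc_scale))
            - np.log1p((sds / pr.re_sd_hc_scale) ** 2) + zsd
        ))
        zc = z[q1 + 1 + r: q1 + 1 + r + self.n_corr]
        if self.n_corr:
            p = np.tanh(zc)
            sh = self._cpc_shapes
            # Beta(sh, sh) on (-1, 1), plus d tanh jacobian log(1 - p^2)
            with np.errstate(divide="ignore"):  # |p| -> 1 gives -inf, as wanted
                total += float(np.sum(
                    (sh - 1.0) * (np.log1p(p) + np.log1p(-p))
                    - special.betaln(sh, sh) - (2.0 * sh - 1.0) * math.log(2.0)
                    + np.log1p(-p**2)
                ))
        for key in self.trans_keys:
            sl = self._trans_slices[key]
            lay = self._trans_layout[key]
            v = z[sl]
            pos = 0
            if lay["family"] == "weibull":
                for zz in v[:2]:
                    x = math.exp(zz)
                    total += (math.log(2.0 / (math.pi * pr.weibull_hc_scale))
                              - math.log1p((x / pr.weibull_hc_scale) ** 2) + zz)
                pos = 2
            elif lay["family"] == "bspline":
                total += float(np.sum(pr.normal_logpdf(v[:lay["n_eta"]], pr.eta_sd)))
                pos = lay["n_eta"]
            else:
                total += float(pr.normal_logpdf(v[0], pr.eta_sd))
                pos = 1
            total += float(np.sum(pr.normal_logpdf(v[pos:pos + lay["n_gamma"]],
                                                   pr.coef_sd)))
            pos += lay["n_gamma"]
            total += float(np.sum(pr.normal_logpdf(v[pos:pos + lay["n_alpha"]],
                                                   pr.coef_sd)))
        return total

    def init_vector(self, mode: str, rng: np.random.Generator) -> np.ndarray:
        z = np.zeros(self.n_params)
        if mode == "random":
            z += 0.5 * rng.standard_normal(self.n_params)
        return z

    def flatten_constrained(self, theta: Mapping) -> np.ndarray:
        """Constrained-scale vector aligned with :attr:`names`."""
        out = [np.asarray(theta["beta"], dtype=float),
               [theta["sigma_e2"]],
               np.asarray(theta["re_sd"], dtype=float)]
        Lc = theta["corr_chol"]
        R = Lc @ Lc.T
        out.append([R[i, j] for i in range(1, self.r) for j in range(i)])
        for key in self.trans_keys:
            p = theta["trans"][key]
            lay = self._trans_layout[key]
            if lay["family"] == "weibull":
                out.append([p["shape"], p["scale"]])
            elif lay["family"] == "bspline":
                out.append(p["eta"])
            else:
                out.append([p["log_ratio"]])
            out.append(p["gamma"])
            out.append(p["alpha"])
        return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float))
                               for x in out if np.size(x)])

    def theta_from_constrained(self, vec: np.ndarray) -> dict:
        """Rebuild the structured parameter dict from a constrained draw."""
        vec = np.asarray(vec, dtype=float)
        q1, r = self.q1, self.r
        pos = 0
        beta = vec[pos:pos + q1]; pos += q1
        sigma_e2 = float(vec[pos]); pos += 1
        sds = vec[pos:pos + r]; pos += r
        R = np.eye(r)
        for i in range(1, r):
            for j in range(i):
                R[i, j] = R[j, i] = vec[pos]
                pos += 1
        Sigma_b = R * np.outer(sds, sds)
        theta = {"beta": beta, "sigma_e2": sigma_e2, "Sigma_b": Sigma_b,
                 "re_sd": sds, "corr_chol": np.linalg.cholesky(R), "trans": {}}
        for key in self.trans_keys:
            lay = self._trans_layout[key]
            p: dict = {}
            if lay["family"] == "weibull":
                p["shape"], p["scale"] = float(vec[pos]), float(vec[pos + 1])
                pos += 2
            elif lay["family"] == "bspline":
                p["eta"] = vec[pos:pos + lay["n_eta"]].copy()
                pos += lay["n_eta"]
            else:
                p["log_ratio"] = float(vec[pos])
                pos += 1
            p["gamma"] = vec[pos:pos + lay["n_gamma"]].copy()
            pos += lay["n_gamma"]
            p["alpha"] = vec[pos:pos + lay["n_alpha"]].copy()
            pos += lay["n_alpha"]
            theta["trans"][key] = p
        return theta


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, draws, params); each chain is split in two
    halves.  Degenerate case: parameters with zero total variance return 1.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[None, :, :]
    c, s, p = draws.shape
    if s < 4:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    half = s // 2
    segs = np.concatenate([draws[:, :half, :], draws[:, half: 2 * half, :]], axis=0)
    m, nn = segs.shape[0], segs.shape[1]
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    Bvar = nn * means.var(axis=0, ddof=1)
    var_hat = (nn - 1) / nn * W + Bvar / nn
    out = np.ones(p)
    ok = W > 0
    out[ok] = np.sqrt(var_hat[ok] / W[ok])
    return out


# --------------------------------------------------------------------------
# posterior fit container
# --------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    """Draws, diagnostics and pointwise log-likelihoods for one estimation run."""

    approach: str
    block: str
    param_names: list[str]
    draws: np.ndarray          # (chains, n_draws, P) constrained scale
    b_draws: np.ndarray        # (chains, n_draws, n, r)
    pointwise: np.ndarray      # (chains, n_draws, n) joint log f(y_i)+log f(E_i)
    members: list[str]
    rhat: np.ndarray
    divergences: int
    accept_rates: dict
    walltime: float
    seed: int
    n_events: int = 0
    pmap: "ParameterMap | None" = None

    @property
    def n_total_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def flat_pointwise(self) -> np.ndarray:
        return self.pointwise.reshape(-1, self.pointwise.shape[-1])

    def posterior_mean(self) -> dict[str, float]:
        flat = self.flat_draws()
        return dict(zip(self.param_names, flat.mean(axis=0)))

    def summary(self):
        import pandas as pd

        flat = self.flat_draws()
        qs = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": qs[0], "q50": qs[1], "q97.5": qs[2],
            "rhat": self.rhat,
        }, index=self.param_names)

    def credible_interval(self, name: str, level: float = 0.95):
        flat = self.flat_draws()[:, self.param_names.index(name)]
        a = 100 * (1 - level) / 2
        return tuple(np.percentile(flat, [a, 100 - a]))


# --------------------------------------------------------------------------
# the adaptive Metropolis-within-Gibbs backend
# --------------------------------------------------------------------------

def _run_chain(
    evaluator: JointEvaluator,
    pmap: ParameterMap,
    config: SamplerConfig,
    rng: np.random.Generator,
):
    """One chain of the adaptive Metropolis-within-Gibbs backend.

    Per sweep: (1) beta by independence-MH from its conjugate LMM
    conditional, corrected for the event terms; (2) sigma_e2 by an exact
    conjugate inverse-gamma Gibbs draw; (3) one adaptive random-walk block
    per transition, re-evaluating only that transition's event terms;
    (4) the random-effects field by a conjugate independence proposal, a
    per-subject random walk, and a joint (b-column, sd) scale move; (5) the
    random-effects covariance by adaptive random walk against
    sum_i log N(b_i; 0, Sigma_b) only.  Association parameters are held at
    zero during the first half of burn-in (phased warm-up).
    """
    n, r = evaluator.n, evaluator.r
    z = pmap.init_vector(config.init, rng)
    tblocks = pmap.trans_blocks()
    nb = len(tblocks)
    log_s = np.full(nb, math.log(0.5))
    run_mean = [z[bl].copy() for bl in tblocks]
    run_cov = [np.eye(len(bl)) * 0.04 for bl in tblocks]
    cov_idx = pmap.cov_idx
    cov_log_s = math.log(0.3)
    cov_run_mean = z[cov_idx].copy()
    cov_run_cov = np.eye(len(cov_idx)) * 0.04
    b_log_s = np.full(n, math.log(0.5))
    scale_log_s = np.full(r, math.log(0.2))
    acc_counts = np.zeros(nb)
    beta_acc = 0.0
    b_acc = 0.0
    divergences = 0

    # fixed pieces for the conjugate beta proposal
    prior_prec = np.eye(pmap.q1) / pmap.priors.coef_sd**2
    XtX = evaluator.X_obs.T @ evaluator.X_obs
    a_ig, b_ig = pmap.priors.sigma_e2_ig
    M_obs = evaluator.y_obs.size
    # per-subject Z'Z blocks for the conjugate random-effects proposal
    lsub, Zo = evaluator.long_subj, evaluator.Z_obs
    ZZ = np.zeros((n, r, r))
    for a in range(r):
        for c in range(r):
            ZZ[:, a, c] = np.bincount(lsub, Zo[:, a] * Zo[:, c], minlength=n) \
                if M_obs else 0.0

    def _conj_b(theta, with_draw_rng=None):
        """Conjugate Gaussian conditional of b given the longitudinal data."""
        s2 = theta["sigma_e2"]
        resid = evaluator.y_obs - evaluator.X_obs @ theta["beta"]
        Zr = np.stack(
            [np.bincount(lsub, Zo[:, a] * resid, minlength=n) for a in range(r)],
            axis=1) if M_obs else np.zeros((n, r))
        Sib = np.linalg.inv(theta["Sigma_b"])
        A = ZZ / s2 + Sib[None, :, :]
        Vb = np.linalg.inv(A)
        mb = np.einsum("nij,nj->ni", Vb, Zr / s2)
        Lvb = np.linalg.cholesky(Vb)
        if with_draw_rng is None:
            return mb, A, Lvb
        eps = with_draw_rng.standard_normal((n, r))
        return mb + np.einsum("nij,nj->ni", Lvb, eps)

    theta = pmap.to_theta(z)
    # start the random-effects field at its conjugate conditional draw given
    # the initial parameters: a zero field would let the covariance updates
    # collapse Sigma_b before the data can inform b
    B = _conj_b(theta, with_draw_rng=rng)
    state = evaluator.full_state(theta, B)
    cur_ll = evaluator.state_total(state)
    cur_lp = pmap.log_prior(z)
    if not np.isfinite(cur_ll + cur_lp):
        raise RuntimeError("initial state has non-finite posterior density")

    total_iter = config.burn_in + config.n_draws * config.thin
    keep_every = config.thin
    draws = np.empty((config.n_draws, pmap.n_params))
    b_draws = np.empty((config.n_draws, n, r))
    pointwise = np.empty((config.n_draws, n))
    kept = 0

    # phased warm-up: association parameters stay at zero for the first half
    # of burn-in so the random-effects field and baselines settle first; on
    # release, the affected blocks' proposal adaptation restarts from the
    # settled state.  Avoids long transients where alpha runs away before b
    # is informed by the data.
    freeze_until = config.burn_in // 2 if pmap.alpha_idx.size else 0
    if freeze_until:
        z[pmap.alpha_idx] = 0.0
        theta = pmap.to_theta(z)
        state = evaluator.full_state(theta, B)
        cur_ll = evaluator.state_total(state)
        cur_lp = pmap.log_prior(z)

    for it in range(total_iter):
        adapting = it < config.burn_in
        gam = (it + 1) ** -0.6
        frozen = it < freeze_until
        if freeze_until and it == freeze_until:
            for bi, bl in enumerate(tblocks):
                if np.intersect1d(bl, pmap.alpha_idx).size:
                    run_cov[bi] = np.eye(len(bl)) * 0.04
                    run_mean[bi] = z[bl].copy()
                    log_s[bi] = math.log(0.5)

        # ---- (1) beta: independence MH from the conjugate LMM conditional --
        s2 = theta["sigma_e2"]
        resid0 = evaluator.y_obs - np.einsum(
            "ij,ij->i", evaluator.Z_obs, B[evaluator.long_subj])
        prec = XtX / s2 + prior_prec
        Vc = np.linalg.inv(prec)
        mc = Vc @ (evaluator.X_obs.T @ resid0) / s2
        Lv = np.linalg.cholesky(Vc)
        beta_prop = mc + Lv @ rng.standard_normal(pmap.q1)
        zprop = z.copy()
        zprop[pmap.beta_idx] = beta_prop
        theta_p = pmap.to_theta(zprop)
        state_p = evaluator.full_state(theta_p, B)
        ll_p = evaluator.state_total(state_p)
        lp_p = pmap.log_prior(zprop)

        def _q(bvec):
            d = bvec - mc
            s = np.linalg.solve(Lv, d)
            return -0.5 * float(s @ s)

        logr = (ll_p + lp_p - _q(beta_prop)) - (cur_ll + cur_lp - _q(z[pmap.beta_idx]))
        if np.isfinite(logr) and math.log(rng.random()) < logr:
            z, theta, state = zprop, theta_p, state_p
            cur_ll, cur_lp = ll_p, lp_p
            beta_acc += 1

        # ---- (2) sigma_e2: exact conjugate Gibbs draw ----------------------
        if M_obs:
            ssr = float(state["ssr_i"].sum())
            s2_new = 1.0 / rng.gamma(a_ig + 0.5 * M_obs, 1.0 / (b_ig + 0.5 * ssr))
            z = z.copy()
            z[pmap.sigma_pos] = math.log(s2_new)
            theta = pmap.to_theta(z)
            state = evaluator.refresh_sigma_e2(state, s2_new)
            cur_ll = evaluator.state_total(state)
            cur_lp = pmap.log_prior(z)

        # ---- (3) per-transition blocks (partial event refresh) -------------
        for bi, bl in enumerate(tblocks):
            d = len(bl)
            scale = math.exp(log_s[bi]) * 2.38 / math.sqrt(d)
            Lp = np.linalg.cholesky(run_cov[bi] + 1e-8 * np.eye(d))
            zprop = z.copy()
            zprop[bl] = z[bl] + scale * (Lp @ rng.standard_normal(d))
            if frozen:
                zprop[pmap.alpha_idx] = z[pmap.alpha_idx]
            theta_p = pmap.to_theta(zprop)
            state_p = evaluator.update_groups(state, theta_p,
                                              evaluator.dependent_groups(bi))
            ll_p = evaluator.state_total(state_p)
            lp_p = pmap.log_prior(zprop)
            logr = (ll_p + lp_p) - (cur_ll + cur_lp)
            if not np.isfinite(logr):
                divergences += int(not np.isfinite(ll_p + lp_p))
                accept = False
            else:
                accept = math.log(rng.random()) < logr
            if accept:
                z, theta, state = zprop, theta_p, state_p
                cur_ll, cur_lp = ll_p, lp_p
                acc_counts[bi] += 1
            if adapting:
                log_s[bi] += gam * ((1.0 if accept else 0.0) - 0.234)
                delta = z[bl] - run_mean[bi]
                run_mean[bi] = run_mean[bi] + gam * delta
                run_cov[bi] = (1 - gam) * run_cov[bi] + gam * np.outer(delta, delta)

        # ---- (4a) random effects: conjugate independence proposal ----------
        # b_i* ~ exact Gaussian conditional given the longitudinal data and
        # Sigma_b; the event terms enter only through the acceptance ratio.
        mb, A, Lvb = _conj_b(theta)
        eps = rng.standard_normal((n, r))
        Bprop = mb + np.einsum("nij,nj->ni", Lvb, eps)
        state_p = evaluator.full_state(theta, Bprop)

        def _qb(Bmat):
            d = Bmat - mb
            return -0.5 * np.einsum("ni,nij,nj->n", d, A, d)

        logr_i = (
            state_p["long"] + evaluator.state_event(state_p) + state_p["bprior"]
            - _qb(Bprop)
            - state["long"] - evaluator.state_event(state) - state["bprior"]
            + _qb(B)
        )
        u = np.log(rng.random(n))
        acc_i = u < np.where(np.isfinite(logr_i), logr_i, -np.inf)
        if acc_i.any():
            state = evaluator.merge_subjects(state, state_p, acc_i)
            B = state["B"]
            cur_ll = evaluator.state_total(state)

        # ---- (4b) random-effects field (per-subject random walk) -----------
        Lb = np.linalg.cholesky(theta["Sigma_b"])
        eps = rng.standard_normal((n, r))
        Bprop = B + np.exp(b_log_s)[:, None] * (eps @ Lb.T)
        state_p = evaluator.full_state(theta, Bprop)
        logr_i = (
            state_p["long"] + evaluator.state_event(state_p) + state_p["bprior"]
            - state["long"] - evaluator.state_event(state) - state["bprior"]
        )
        u = np.log(rng.random(n))
        acc_i = u < np.where(np.isfinite(logr_i), logr_i, -np.inf)
        if acc_i.any():
            state = evaluator.merge_subjects(state, state_p, acc_i)
            B = state["B"]
            cur_ll = evaluator.state_total(state)
        if adapting:
            b_log_s += gam * (acc_i.astype(float) - 0.3)
        b_acc += acc_i.mean()

        # ---- (4c) joint scale move per random-effect column ----------------
        # rescale (b_{.k}, sd_k) together: the standardised effects are
        # unchanged, so the b-prior quadratic form is invariant and the
        # n*log(c) Jacobian cancels the log-determinant change; acceptance is
        # driven by the likelihood, traversing the sd_k <-> sigma_e2 ridge.
        for k in range(r):
            epsk = math.exp(scale_log_s[k]) * rng.standard_normal()
            c = math.exp(epsk)
            zprop = z.copy()
            zprop[pmap.q1 + 1 + k] += epsk
            theta_p = pmap.to_theta(zprop)
            Bprop = B.copy()
            Bprop[:, k] *= c
            state_p = evaluator.full_state(theta_p, Bprop)
            ll_p = evaluator.state_total(state_p)
            lp_p = pmap.log_prior(zprop)
            logr = (ll_p + lp_p) - (cur_ll + cur_lp) + n * epsk
            accept = np.isfinite(logr) and math.log(rng.random()) < logr
            if accept:
                z, theta, state = zprop, theta_p, state_p
                B = state["B"]
                cur_ll, cur_lp = ll_p, lp_p
            if adapting:
                scale_log_s[k] += gam * ((1.0 if accept else 0.0) - 0.44)

        # ---- (5) Sigma_b: random walk against the b prior only -------------
        for _ in range(3):
            d = len(cov_idx)
            scale = math.exp(cov_log_s) * 2.38 / math.sqrt(d)
            Lp = np.linalg.cholesky(cov_run_cov + 1e-8 * np.eye(d))
            zprop = z.copy()
            zprop[cov_idx] = z[cov_idx] + scale * (Lp @ rng.standard_normal(d))
            theta_p = pmap.to_theta(zprop)
            state_p = evaluator.refresh_bprior(state, theta_p["Sigma_b"])
            ll_p = evaluator.state_total(state_p)
            lp_p = pmap.log_prior(zprop)
            logr = (ll_p + lp_p) - (cur_ll + cur_lp)
            accept = np.isfinite(logr) and math.log(rng.random()) < logr
            if accept:
                z, theta, state = zprop, theta_p, state_p
                cur_ll, cur_lp = ll_p, lp_p
            if adapting:
                cov_log_s += gam * ((1.0 if accept else 0.0) - 0.234)
                delta = z[cov_idx] - cov_run_mean
                cov_run_mean = cov_run_mean + gam * delta
                cov_run_cov = (1 - gam) * cov_run_cov + gam * np.outer(delta, delta)

        # ---- record ----
        if it >= config.burn_in and (it - config.burn_in) % keep_every == 0 \
                and kept < config.n_draws:
            draws[kept] = pmap.flatten_constrained(theta)
            b_draws[kept] = B
            pointwise[kept] = state["long"] + evaluator.state_event(state)
            kept += 1

    info = {
        "theta_accept": (acc_counts / total_iter).tolist(),
        "beta_accept": beta_acc / total_iter,
        "b_accept": b_acc / total_iter,
    }
    return draws, b_draws, pointwise, divergences, info


def _fit_single(
    evaluator: JointEvaluator,
    pmap: ParameterMap,
    config: SamplerConfig,
    approach: str,
    block_tag: str,
    members: list[str],
    n_events: int,
) -> PosteriorFit:
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.chains)
    all_draws, all_b, all_pw = [], [], []
    divergences = 0
    info = {}
    for ci in range(config.chains):
        rng = np.random.Generator(np.random.Philox(child[ci]))
        d, bd, pw, div, info = _run_chain(evaluator, pmap, config, rng)
        all_draws.append(d)
        all_b.append(bd)
        all_pw.append(pw)
        divergences += div
    draws = np.stack(all_draws)
    rhat = (split_rhat(draws) if config.n_draws >= 4
            else np.full(pmap.n_params, np.nan))
    fit = PosteriorFit(
        approach=approach,
        block=block_tag,
        param_names=list(pmap.names),
        draws=draws,
        b_draws=np.stack(all_b),
        pointwise=np.stack(all_pw),
        members=members,
        rhat=rhat,
        divergences=int(divergences),
        accept_rates=info,
        walltime=time.perf_counter() - t0,
        seed=config.seed,
        n_events=n_events,
        pmap=pmap,
    )
    bad = [nm for nm, rh in zip(fit.param_names, fit.rhat) if rh > 1.1]
    if bad:
        logger.info("%s %s: R-hat > 1.1 for %s", approach, block_tag, bad)
    if n_events == 0:
        logger.warning("%s %s: no observed events; association posterior is "
                       "prior-dominated", approach, block_tag)
    return fit


def _reanchored_subspec(spec: JointModelSpec, trans_keys) -> JointModelSpec:
    """Block-local spec: proportional baselines whose anchor lies outside the
    block are promoted to free splines (first per anchor) or re-anchored
    within the block, keeping every block parameter identifiable."""
    keys = list(trans_keys)
    inside = set(keys)
    promoted: dict[tuple[int, int], tuple[int, int]] = {}
    new_trans = {}
    for key in keys:
        tm = spec.transitions[key]
        bl = tm.baseline
        if isinstance(bl, ProportionalBaseline) and bl.anchor not in inside:
            anchor_tm = spec.transitions[bl.anchor]
            if bl.anchor in promoted:
                bl = ProportionalBaseline(promoted[bl.anchor], bl.log_ratio)
            else:
                src = anchor_tm.baseline
                # B-spline bases sum to one on the clamped window, so adding
                # log_ratio to every coefficient shifts log h0 by log_ratio
                bl = BSplineLogBaseline(
                    coefs=np.asarray(src.coefs, dtype=float) + bl.log_ratio,
                    knots=src.knots, degree=src.degree,
                )
                promoted[tm.baseline.anchor] = key
        new_trans[key] = TransitionModel(
            transition=key, baseline=bl, timescale=tm.timescale,
            gamma=tm.gamma, association=tm.association,
        )
    from .state_graph import TransitionGraph

    return JointModelSpec(
        graph=TransitionGraph(keys),
        longitudinal=spec.longitudinal,
        transitions=new_trans,
    )


# --------------------------------------------------------------------------
# public fitting API
# --------------------------------------------------------------------------

def fit_jm_msm(
    subjects: Sequence[SubjectRecord],
    spec: JointModelSpec,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorFit:
    """Sample the full joint posterior over (Theta, b) on all data."""
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    rule = gauss_legendre_rule(config.quad_points)
    evaluator = JointEvaluator.for_full_data(list(subjects), spec, rule)
    pmap = ParameterMap(spec, list(spec.graph.transitions), priors)
    n_events = sum(s.n_transitions for s in subjects)
    return _fit_single(evaluator, pmap, config, "jm-msm", "full",
                       [s.id for s in subjects], n_events)


def _fit_blocks(blocks_data, spec, priors, config, approach, n_jobs):
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    rule = gauss_legendre_rule(config.quad_points)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(blocks_data))]

    def one(args):
        bd, seed = args
        if bd.n == 0:
            logger.warning("%s: empty block %s skipped", approach, bd.block)
            return None
        sub_spec = _reanchored_subspec(spec, list(bd.block.transitions))
        evaluator = JointEvaluator.for_block(bd, sub_spec, rule)
        pmap = ParameterMap(sub_spec, list(bd.block.transitions), priors)
        cfg = SamplerConfig(**{**config.__dict__, "seed": seed})
        n_events = int((bd.event_target >= 0).sum())
        return _fit_single(evaluator, pmap, cfg, approach, str(bd.block),
                           bd.members, n_events)

    tasks = list(zip(blocks_data, seeds))
    if n_jobs and n_jobs != 1:
        from joblib import Parallel, delayed

        fits = Parallel(n_jobs=n_jobs)(delayed(one)(t) for t in tasks)
    else:
        fits = [one(t) for t in tasks]
    return [f for f in fits if f is not None]


def fit_jm_cr(
    subjects: Sequence[SubjectRecord],
    spec: JointModelSpec,
    priors: PriorSpec | None = None,
    strategy: str = "historical",
    config: SamplerConfig | None = None,
    n_jobs: int = 1,
) -> list[PosteriorFit]:
    """Independent posterior sampling per competing-risk block."""
    blocks = competing_risk_blocks(spec.graph)
    data = [build_block_dataset(subjects, blk, strategy) for blk in blocks]
    return _fit_blocks(data, spec, priors, config, "jm-cr", n_jobs)


def fit_jm_st(
    subjects: Sequence[SubjectRecord],
    spec: JointModelSpec,
    priors: PriorSpec | None = None,
    strategy: str = "historical",
    config: SamplerConfig | None = None,
    n_jobs: int = 1,
) -> list[PosteriorFit]:
    """Independent posterior sampling per permitted transition."""
    from .data_model import single_transition_view

    data = []
    for blk in competing_risk_blocks(spec.graph):
        bd = build_block_dataset(subjects, blk, strategy)
        for k in blk.terminal_states:
            data.append(single_transition_view(bd, k))
    return _fit_blocks(data, spec, priors, config, "jm-st", n_jobs)
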