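"""Log-likelihood components for the joint longitudinal-multistate model.

Two layers live here.  The reference layer implements the per-subject
log-likelihoods directly from their definitions: the Gaussian longitudinal
terms, the full multistate likelihood (event log-hazards at observed
transition times minus cumulative intensities over every sojourn, summed over
all transitions leaving the occupied state), the competing-risk block
likelihood and the single-transition survival likelihood.  Cumulative
intensities are approximated by Gauss-Legendre quadrature (15 points by
default) after affine mapping of the nodes onto each exposure interval.

The second layer, :class:`JointEvaluator`, precomputes design matrices and
quadrature grids once per dataset and evaluates all per-subject components
for a candidate parameter set with vectorised array operations; the MCMC
backend and the LOO machinery run on it.

For unidirectional processes the likelihood factorises exactly: per subject,
the full multistate log-likelihood equals the sum of competing-risk block
log-likelihoods over the blocks the subject enters, and each block
log-likelihood equals the sum of its cause-specific single-transition
log-likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .data_model import BlockDataset, SubjectRecord
from .model_spec import (
    BSplineLogBaseline,
    JointModelSpec,
    LongitudinalSubmodel,
    PriorSpec,
    ProportionalBaseline,
    TransitionModel,
    WeibullBaseline,
    hazard,
    log_prior,
)

__all__ = [
    "QuadratureRule",
    "gauss_legendre_rule",
    "LogLikComponents",
    "longitudinal_loglik",
    "cumulative_hazard",
    "multistate_loglik",
    "competing_risk_loglik",
    "single_transition_loglik",
    "log_posterior_kernel",
    "theta_from_spec",
    "JointEvaluator",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Legendre nodes/weights on [-1, 1]."""

    nodes: np.ndarray
    weights: np.ndarray

    @property
    def count(self) -> int:
        return len(self.nodes)


@lru_cache(maxsize=8)
def gauss_legendre_rule(count: int = 15) -> QuadratureRule:
    nodes, weights = np.polynomial.legendre.leggauss(count)
    return QuadratureRule(nodes=nodes, weights=weights)


def _mvn_logpdf_rows(B: np.ndarray, Sigma: np.ndarray, r: int) -> np.ndarray:
    """Row-wise N(0, Sigma) log density; -inf if Sigma is not valid SPD."""
    Sigma = np.asarray(Sigma, dtype=float)
    n = B.shape[0]
    if not np.all(np.isfinite(Sigma)):
        return np.full(n, -np.inf)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return np.full(n, -np.inf)
    sol = np.linalg.solve(L, B.T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (r * _LOG_2PI + logdet) - 0.5 * np.sum(sol**2, axis=0)


@dataclass
class LogLikComponents:
    """Per-subject longitudinal and event log-likelihoods plus totals."""

    longitudinal: np.ndarray
    event: np.ndarray

    @property
    def pointwise(self) -> np.ndarray:
        return self.longitudinal + self.event

    @property
    def total(self) -> float:
        return float(self.longitudinal.sum() + self.event.sum())


# --------------------------------------------------------------------------
# reference implementations
# --------------------------------------------------------------------------

def longitudinal_loglik(
    subject: SubjectRecord,
    long_index: np.ndarray,
    long_model: LongitudinalSubmodel,
    b=None,
    beta=None,
    sigma_e2: float | None = None,
) -> float:
    """Gaussian log density of the indexed measurements given b."""
    s2 = long_model.sigma_e2 if sigma_e2 is None else sigma_e2
    if s2 is None or s2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    idx = np.asarray(long_index, dtype=int)
    if idx.size == 0:
        return 0.0
    t = subject.obs_times[idx]
    y = subject.obs_values[idx]
    m = long_model.mu(t, subject.covariates, beta, b)
    return float(-0.5 * idx.size * (_LOG_2PI + math.log(s2))
                 - 0.5 * np.sum((y - m) ** 2) / s2)


def cumulative_hazard(
    t0: float,
    t1: float,
    state_entry_time: float,
    w,
    trans_model: TransitionModel,
    long_model: LongitudinalSubmodel,
    b=None,
    rule: QuadratureRule | None = None,
    beta=None,
    spec: JointModelSpec | None = None,
) -> float:
    """Gauss-Legendre approximation of the integral of h over [t0, t1]."""
    if t1 < t0 - 1e-12:
        raise ValueError("cumulative_hazard requires t0 <= t1")
    if t1 <= t0:
        return 0.0
    rule = rule or gauss_legendre_rule()
    half = 0.5 * (t1 - t0)
    mid = 0.5 * (t0 + t1)
    u = mid + half * rule.nodes
    h = hazard(u, state_entry_time, w, trans_model, long_model, b, beta, spec)
    return float(half * np.sum(rule.weights * h))


def multistate_loglik(
    subject: SubjectRecord,
    spec: JointModelSpec,
    b=None,
    rule: QuadratureRule | None = None,
) -> float:
    """Full multistate log-likelihood contribution of one subject.

    Over each sojourn in state j (interval (T_{l-1}, T_l]), subtract the
    cumulative intensity of every transition leaving j, and add the
    log-intensity of the realised transition at T_l when one occurs; the
    censored final interval contributes survival terms only.
    """
    subject.validate_against(spec.graph)
    rule = rule or gauss_legendre_rule()
    total = 0.0
    for state, entry, exit_t, nxt in subject.sojourns():
        for k in spec.graph.successors(state):
            tm = spec.transitions[(state, k)]
            total -= cumulative_hazard(
                entry, exit_t, entry, subject.covariates, tm,
                spec.longitudinal, b, rule, spec=spec,
            )
            if nxt == k:
                h = hazard(exit_t, entry, subject.covariates, tm,
                           spec.longitudinal, b, spec=spec)
                total += float(np.log(h[0])) if h[0] > 0 else -np.inf
    return total


def competing_risk_loglik(
    block_dataset: BlockDataset,
    member: int,
    spec: JointModelSpec,
    b=None,
    rule: QuadratureRule | None = None,
) -> float:
    """Competing-risk block log-likelihood for one member subject."""
    rule = rule or gauss_legendre_rule()
    s = block_dataset.subjects[member]
    entry = float(block_dataset.entry[member])
    exit_t = float(block_dataset.exit[member])
    target = int(block_dataset.event_target[member])
    total = 0.0
    for j, k in block_dataset.block.transitions:
        tm = spec.transitions[(j, k)]
        total -= cumulative_hazard(entry, exit_t, entry, s.covariates, tm,
                                   spec.longitudinal, b, rule, spec=spec)
        if target == k:
            h = hazard(exit_t, entry, s.covariates, tm, spec.longitudinal,
                       b, spec=spec)
            total += float(np.log(h[0])) if h[0] > 0 else -np.inf
    return total


def single_transition_loglik(
    st_view: BlockDataset,
    member: int,
    spec: JointModelSpec,
    b=None,
    rule: QuadratureRule | None = None,
) -> float:
    """Standard survival log-likelihood for one member of a single-transition view."""
    return competing_risk_loglik(st_view, member, spec, b, rule)


# --------------------------------------------------------------------------
# structured parameter dicts
# --------------------------------------------------------------------------

def theta_from_spec(spec: JointModelSpec) -> dict:
    """Extract the structured parameter dict from a fully-valued spec."""
    lm = spec.longitudinal
    if lm.beta is None or lm.sigma_e2 is None or lm.Sigma_b is None:
        raise ValueError("spec carries no longitudinal parameter values")
    theta: dict = {
        "beta": np.asarray(lm.beta, dtype=float),
        "sigma_e2": float(lm.sigma_e2),
        "Sigma_b": np.asarray(lm.Sigma_b, dtype=float),
        "trans": {},
    }
    for key, tm in spec.transitions.items():
        bl = tm.baseline
        if isinstance(bl, WeibullBaseline):
            base = {"shape": bl.shape, "scale": bl.scale}
        elif isinstance(bl, BSplineLogBaseline):
            base = {"eta": np.asarray(bl.coefs, dtype=float)}
        else:
            base = {"log_ratio": float(bl.log_ratio)}
        need = tm.association.arity(lm.r)
        theta["trans"][key] = {
            **base,
            "gamma": np.asarray(tm.gamma, dtype=float),
            "alpha": np.asarray(tm.association.alpha[:need], dtype=float),
        }
    return theta


# --------------------------------------------------------------------------
# vectorised evaluator
# --------------------------------------------------------------------------

class JointEvaluator:
    """Precompiled per-dataset likelihood evaluator.

    Holds flattened quadrature-node and event-row arrays with their design
    matrices; :meth:`components` returns per-subject longitudinal, event and
    random-effect-prior log-likelihood vectors for a structured parameter
    dict ``theta`` and an (n, r) random-effects matrix ``B``.
    """

    def __init__(
        self,
        spec: JointModelSpec,
        trans_keys: Sequence[tuple[int, int]],
        n_subjects: int,
        W: np.ndarray,
        long_subj: np.ndarray,
        X_obs: np.ndarray,
        Z_obs: np.ndarray,
        y_obs: np.ndarray,
        int_subj: np.ndarray,
        int_trans: np.ndarray,
        int_t0: np.ndarray,
        int_t1: np.ndarray,
        int_entry: np.ndarray,
        ev_subj: np.ndarray,
        ev_trans: np.ndarray,
        ev_time: np.ndarray,
        ev_entry: np.ndarray,
        rule: QuadratureRule,
    ) -> None:
        self.spec = spec
        self.trans_keys = list(trans_keys)
        self.n = int(n_subjects)
        self.W = W
        self.rule = rule
        lm = spec.longitudinal
        self.r = lm.r
        # longitudinal rows
        self.long_subj = long_subj
        self.X_obs, self.Z_obs, self.y_obs = X_obs, Z_obs, y_obs
        self.n_obs_i = np.bincount(long_subj, minlength=self.n).astype(float)
        # quadrature nodes, flattened (n_int * Q,)
        Q = rule.count
        half = 0.5 * (int_t1 - int_t0)
        mid = 0.5 * (int_t0 + int_t1)
        u = (mid[:, None] + half[:, None] * rule.nodes[None, :])
        self.n_int = len(int_t0)
        self.int_subj = int_subj
        self.node_hw = half[:, None] * rule.weights[None, :]  # (n_int, Q)
        node_u = u.ravel()
        node_trans = np.repeat(int_trans, Q)
        node_subj = np.repeat(int_subj, Q)
        clock_reset = spec.timescale == "clock_reset"
        node_B = node_u - np.repeat(int_entry, Q) if clock_reset else node_u
        ev_B = ev_time - ev_entry if clock_reset else ev_time
        self.node_subj = node_subj
        self.ev_subj = ev_subj

        needs_mu = any(
            spec.transitions[k].association.kind in (
                "current_value", "current_value_quadratic",
                "current_value_by_covariate")
            for k in self.trans_keys
        )
        needs_slope = any(
            spec.transitions[k].association.needs_slope for k in self.trans_keys
        )
        needs_re = any(
            spec.transitions[k].association.kind == "shared_random_effects"
            for k in self.trans_keys
        )
        self._needs_mu, self._needs_slope, self._needs_re = needs_mu, needs_slope, needs_re

        # mu design at node/event STUDY times; the fixed basis may depend on
        # w_i, so rows are evaluated grouped by subject
        self.X_node = self._grouped_fixed_design(lm, node_u, node_subj)
        self.Z_node = lm.random_basis(node_u) if len(node_u) else np.zeros((0, lm.r))
        self.X_ev = self._grouped_fixed_design(lm, ev_time, ev_subj)
        self.Z_ev = lm.random_basis(ev_time) if len(ev_time) else np.zeros((0, lm.r))
        if needs_slope:
            self.dX_node = self._grouped_fixed_design(lm, node_u, node_subj, deriv=True)
            self.dZ_node = lm.random_basis_deriv(node_u)
            self.dX_ev = self._grouped_fixed_design(lm, ev_time, ev_subj, deriv=True)
            self.dZ_ev = lm.random_basis_deriv(ev_time)

        # per-transition row groups and baseline precomputations
        self.groups = []
        with np.errstate(divide="ignore"):
            log_node_B = np.where(node_B > 0, np.log(np.maximum(node_B, 1e-300)), -np.inf)
            log_ev_B = np.where(ev_B > 0, np.log(np.maximum(ev_B, 1e-300)), -np.inf)
        hw_flat = self.node_hw.ravel()
        for ti, key in enumerate(self.trans_keys):
            tm = spec.transitions[key]
            nsel = np.flatnonzero(node_trans == ti)
            esel = np.flatnonzero(ev_trans == ti)
            baseline, _ = spec.resolved_baseline(key)
            g = {
                "key": key, "tm": tm, "nsel": nsel, "esel": esel,
                "node_w": W[node_subj[nsel]] if W.size else np.zeros((nsel.size, 0)),
                "ev_w": W[ev_subj[esel]] if W.size else np.zeros((esel.size, 0)),
                "node_hw": hw_flat[nsel],
                "node_subj": node_subj[nsel],
                "ev_subj_g": ev_subj[esel],
            }
            if isinstance(baseline, WeibullBaseline):
                g["family"] = "weibull"
                g["log_node_B"] = log_node_B[nsel]
                g["log_ev_B"] = log_ev_B[esel]
            else:
                g["family"] = "spline"
                g["S_node"] = baseline.basis_matrix(node_B[nsel]) if nsel.size else np.zeros((0, baseline.n_params))
                g["S_ev"] = baseline.basis_matrix(ev_B[esel]) if esel.size else np.zeros((0, baseline.n_params))
                if isinstance(tm.baseline, ProportionalBaseline):
                    g["anchor"] = tm.baseline.anchor
            self.groups.append(g)

    def _grouped_fixed_design(self, lm, tvec, subj, deriv=False):
        """Fixed-effects design at times ``tvec``; basis may depend on w_i."""
        fn = lm.fixed_basis_deriv if deriv else lm.fixed_basis
        out = np.zeros((len(tvec), lm.q1))
        if len(tvec) == 0:
            return out
        order = np.argsort(subj, kind="stable")
        sorted_subj = subj[order]
        bounds = list(np.flatnonzero(np.diff(sorted_subj)) + 1)
        start = 0
        for end in bounds + [len(order)]:
            rows = order[start:end]
            start = end
            if rows.size == 0:
                continue
            w = self.W[subj[rows[0]]] if self.W.size else np.zeros(0)
            out[rows] = fn(tvec[rows], w)
        return out

    # ---- construction helpers -------------------------------------------

    @classmethod
    def for_full_data(
        cls,
        subjects: Sequence[SubjectRecord],
        spec: JointModelSpec,
        rule: QuadratureRule | None = None,
    ) -> "JointEvaluator":
        """Evaluator targeting the full multistate likelihood (JM-MSM)."""
        rule = rule or gauss_legendre_rule()
        trans_keys = list(spec.graph.transitions)
        tindex = {k: i for i, k in enumerate(trans_keys)}
        W = np.array([s.covariates for s in subjects], dtype=float)
        ls, Xs, Zs, ys = [], [], [], []
        lm = spec.longitudinal
        ints, evs = [], []
        for i, s in enumerate(subjects):
            if s.obs_times.size:
                ls.append(np.full(s.obs_times.size, i))
                Xs.append(lm.fixed_basis(s.obs_times, s.covariates))
                Zs.append(lm.random_basis(s.obs_times))
                ys.append(s.obs_values)
            for state, entry, exit_t, nxt in s.sojourns():
                for k in spec.graph.successors(state):
                    ints.append((i, tindex[(state, k)], entry, exit_t, entry))
                    if nxt == k:
                        evs.append((i, tindex[(state, k)], exit_t, entry))
        return cls._assemble(spec, trans_keys, len(subjects), W,
                             ls, Xs, Zs, ys, ints, evs, rule)

    @classmethod
    def for_block(
        cls,
        bd: BlockDataset,
        spec: JointModelSpec,
        rule: QuadratureRule | None = None,
    ) -> "JointEvaluator":
        """Evaluator for a competing-risk block or single-transition view."""
        rule = rule or gauss_legendre_rule()
        trans_keys = list(bd.block.transitions)
        tindex = {k: i for i, k in enumerate(trans_keys)}
        W = np.array([s.covariates for s in bd.subjects], dtype=float)
        lm = spec.longitudinal
        ls, Xs, Zs, ys = [], [], [], []
        ints, evs = [], []
        for i, s in enumerate(bd.subjects):
            idx = bd.long_index[i]
            if idx.size:
                t = s.obs_times[idx]
                ls.append(np.full(idx.size, i))
                Xs.append(lm.fixed_basis(t, s.covariates))
                Zs.append(lm.random_basis(t))
                ys.append(s.obs_values[idx])
            entry, exit_t = float(bd.entry[i]), float(bd.exit[i])
            target = int(bd.event_target[i])
            for j, k in trans_keys:
                ti = tindex[(j, k)]
                ints.append((i, ti, entry, exit_t, entry))
                if target == k:
                    evs.append((i, ti, exit_t, entry))
        return cls._assemble(spec, trans_keys, bd.n, W,
                             ls, Xs, Zs, ys, ints, evs, rule)

    @classmethod
    def _assemble(cls, spec, trans_keys, n, W, ls, Xs, Zs, ys, ints, evs, rule):
        lm = spec.longitudinal
        long_subj = np.concatenate(ls).astype(int) if ls else np.zeros(0, dtype=int)
        X_obs = np.vstack(Xs) if Xs else np.zeros((0, lm.q1))
        Z_obs = np.vstack(Zs) if Zs else np.zeros((0, lm.r))
        y_obs = np.concatenate(ys) if ys else np.zeros(0)
        ia = np.array(ints, dtype=float).reshape(-1, 5)
        ea = np.array(evs, dtype=float).reshape(-1, 4)
        return cls(
            spec, trans_keys, n, W, long_subj, X_obs, Z_obs, y_obs,
            ia[:, 0].astype(int), ia[:, 1].astype(int), ia[:, 2], ia[:, 3], ia[:, 4],
            ea[:, 0].astype(int), ea[:, 1].astype(int), ea[:, 2], ea[:, 3],
            rule,
        )

    # ---- evaluation ------------------------------------------------------

    def _group_loghaz(self, g, tpar, B, mu_node, dmu_node, mu_ev, dmu_ev):
        """(log h at this group's node rows, log h at its event rows)."""
        key, tm = g["key"], g["tm"]
        p = tpar[key]
        nsel, esel = g["nsel"], g["esel"]
        if g["family"] == "weibull":
            shape, scale = float(p["shape"]), float(p["scale"])
            lh_n = math.log(shape) + (shape - 1.0) * g["log_node_B"] + math.log(scale)
            lh_e = math.log(shape) + (shape - 1.0) * g["log_ev_B"] + math.log(scale)
        else:
            if "anchor" in g:
                eta = np.asarray(tpar[g["anchor"]]["eta"], dtype=float)
                off = float(p["log_ratio"])
            else:
                eta = np.asarray(p["eta"], dtype=float)
                off = 0.0
            lh_n = g["S_node"] @ eta + off
            lh_e = g["S_ev"] @ eta + off
        gamma = np.asarray(p["gamma"], dtype=float)
        if gamma.size:
            lh_n = lh_n + g["node_w"] @ gamma
            lh_e = lh_e + g["ev_w"] @ gamma
        assoc = tm.association
        if assoc.kind != "none":
            alpha = np.asarray(p["alpha"], dtype=float)
            ci = assoc.covariate_index
            wc_n = g["node_w"][:, ci] if ci is not None else None
            wc_e = g["ev_w"][:, ci] if ci is not None else None
            lh_n = lh_n + assoc.term(
                alpha,
                mu_node[nsel] if mu_node is not None else None,
                dmu_node[nsel] if dmu_node is not None else None,
                B[g["node_subj"]], wc_n,
            )
            lh_e = lh_e + assoc.term(
                alpha,
                mu_ev[esel] if mu_ev is not None else None,
                dmu_ev[esel] if dmu_ev is not None else None,
                B[g["ev_subj_g"]], wc_e,
            )
        return lh_n, lh_e

    def _group_part(self, g, lh_n, lh_e) -> np.ndarray:
        """Per-subject event log-lik contribution of one transition group."""
        with np.errstate(over="ignore"):  # inf cumhaz => -inf part => rejection
            w = np.exp(lh_n) * g["node_hw"]
        cum = np.bincount(g["node_subj"], weights=w,
                          minlength=self.n) if lh_n.size else np.zeros(self.n)
        ev = np.bincount(g["ev_subj_g"], weights=lh_e, minlength=self.n) \
            if lh_e.size else np.zeros(self.n)
        return ev - cum

    def _trajectories(self, beta, B):
        mu_node = dmu_node = mu_ev = dmu_ev = None
        if self._needs_mu:
            mu_node = self.X_node @ beta + np.einsum(
                "ij,ij->i", self.Z_node, B[self.node_subj])
            mu_ev = self.X_ev @ beta + np.einsum(
                "ij,ij->i", self.Z_ev, B[self.ev_subj])
        if self._needs_slope:
            dmu_node = self.dX_node @ beta + np.einsum(
                "ij,ij->i", self.dZ_node, B[self.node_subj])
            dmu_ev = self.dX_ev @ beta + np.einsum(
                "ij,ij->i", self.dZ_ev, B[self.ev_subj])
        return mu_node, dmu_node, mu_ev, dmu_ev

    def full_state(self, theta: Mapping, B: np.ndarray) -> dict:
        """Evaluate everything; the returned state supports partial updates."""
        B = np.asarray(B, dtype=float).reshape(self.n, self.r)
        beta = np.asarray(theta["beta"], dtype=float)
        s2 = float(theta["sigma_e2"])
        if self.y_obs.size:
            mu_obs = self.X_obs @ beta + np.einsum(
                "ij,ij->i", self.Z_obs, B[self.long_subj])
            ssr_i = np.bincount(self.long_subj,
                                weights=(self.y_obs - mu_obs) ** 2,
                                minlength=self.n)
        else:
            ssr_i = np.zeros(self.n)
        long = (-0.5 * (_LOG_2PI + math.log(s2)) * self.n_obs_i
                - 0.5 * ssr_i / s2)
        mu_node, dmu_node, mu_ev, dmu_ev = self._trajectories(beta, B)
        parts = np.empty((len(self.groups), self.n))
        for gi, g in enumerate(self.groups):
            lh_n, lh_e = self._group_loghaz(g, theta["trans"], B,
                                            mu_node, dmu_node, mu_ev, dmu_ev)
            parts[gi] = self._group_part(g, lh_n, lh_e)
        bprior = _mvn_logpdf_rows(B, theta["Sigma_b"], self.r)
        return {
            "B": B, "long": long, "bprior": bprior, "parts": parts,
            "ssr_i": ssr_i,
            "mu_node": mu_node, "dmu_node": dmu_node,
            "mu_ev": mu_ev, "dmu_ev": dmu_ev,
        }

    def refresh_sigma_e2(self, state: dict, s2: float) -> dict:
        """New state after a sigma_e2-only change (residuals unchanged)."""
        new = dict(state)
        new["long"] = (-0.5 * (_LOG_2PI + math.log(s2)) * self.n_obs_i
                       - 0.5 * state["ssr_i"] / s2)
        return new

    def refresh_bprior(self, state: dict, Sigma_b: np.ndarray) -> dict:
        """New state after a Sigma_b-only change (b unchanged)."""
        new = dict(state)
        new["bprior"] = _mvn_logpdf_rows(state["B"], Sigma_b, self.r)
        return new

    def update_groups(self, state: dict, theta: Mapping,
                      group_ids: Sequence[int]) -> dict:
        """New state with only the given transition groups re-evaluated.

        Valid only when ``theta['beta']``, ``Sigma_b``/``sigma_e2`` and B are
        unchanged relative to the cached state.
        """
        new = dict(state)
        new["parts"] = state["parts"].copy()
        for gi in group_ids:
            g = self.groups[gi]
            lh_n, lh_e = self._group_loghaz(
                g, theta["trans"], state["B"],
                state["mu_node"], state["dmu_node"],
                state["mu_ev"], state["dmu_ev"],
            )
            new["parts"][gi] = self._group_part(g, lh_n, lh_e)
        return new

    def dependent_groups(self, group_id: int) -> list[int]:
        """Groups whose hazard depends on group_id's parameters (anchor links)."""
        key = self.trans_keys[group_id]
        out = [group_id]
        for gi, g in enumerate(self.groups):
            if gi != group_id and g.get("anchor") == key:
                out.append(gi)
        return out

    def merge_subjects(self, state: dict, state_p: dict,
                       accept: np.ndarray) -> dict:
        """Combine two states subject-wise (used by per-subject b updates).

        Every cached quantity is attributable to a single subject, so the
        merge is exact: accepted subjects take all their rows/columns from
        ``state_p``.
        """
        out = dict(state)
        out["B"] = np.where(accept[:, None], state_p["B"], state["B"])
        out["long"] = np.where(accept, state_p["long"], state["long"])
        out["bprior"] = np.where(accept, state_p["bprior"], state["bprior"])
        out["ssr_i"] = np.where(accept, state_p["ssr_i"], state["ssr_i"])
        out["parts"] = np.where(accept[None, :], state_p["parts"], state["parts"])
        for mk, subj in (("mu_node", self.node_subj), ("dmu_node", self.node_subj),
                         ("mu_ev", self.ev_subj), ("dmu_ev", self.ev_subj)):
            if state[mk] is not None:
                arr = state[mk].copy()
                m = accept[subj]
                arr[m] = state_p[mk][m]
                out[mk] = arr
        return out

    @staticmethod
    def state_event(state: dict) -> np.ndarray:
        return state["parts"].sum(axis=0)

    @staticmethod
    def state_total(state: dict) -> float:
        return float(state["long"].sum() + state["parts"].sum()
                     + state["bprior"].sum())

    def components(self, theta: Mapping, B: np.ndarray) -> dict[str, np.ndarray]:
        """Per-subject log-likelihood components at ``theta`` and ``B``.

        Returns ``{"long": (n,), "event": (n,), "bprior": (n,)}``.
        """
        st = self.full_state(theta, B)
        return {"long": st["long"], "event": self.state_event(st),
                "bprior": st["bprior"]}

    def total(self, theta: Mapping, B: np.ndarray) -> float:
        return self.state_total(self.full_state(theta, B))

    def pointwise(self, theta: Mapping, B: np.ndarray) -> np.ndarray:
        """Per-subject joint log f(y_i | b_i) + log f(event_i | b_i)."""
        c = self.components(theta, B)
        return c["long"] + c["event"]

    def loglik_components(self, theta: Mapping, B: np.ndarray) -> LogLikComponents:
        """Per-subject longitudinal and event log-likelihood vectors."""
        c = self.components(theta, B)
        return LogLikComponents(longitudinal=c["long"], event=c["event"])


def log_posterior_kernel(
    approach: str,
    data,
    spec: JointModelSpec,
    priors: PriorSpec,
    b: np.ndarray,
    rule: QuadratureRule | None = None,
    strategy: str = "historical",
) -> float:
    """Unnormalised log posterior of (Theta, b) for one inference approach.

    ``approach`` is one of ``jm-msm`` (data = list of subjects), ``jm-cr`` or
    ``jm-st`` (data = a BlockDataset built for the corresponding block).
    Parameter values are taken from the spec; ``b`` is the (n, r)
    random-effects matrix over the approach's subjects.
    """
    rule = rule or gauss_legendre_rule()
    approach = approach.lower()
    theta = theta_from_spec(spec)
    if approach == "jm-msm":
        ev = JointEvaluator.for_full_data(list(data), spec, rule)
    elif approach in ("jm-cr", "jm-st"):
        ev = JointEvaluator.for_block(data, spec, rule)
    else:
        raise ValueError(f"unknown approach {approach!r}")
    lp = log_prior(spec, priors)
    if not np.isfinite(lp):
        return -np.inf
    return ev.total(theta, np.asarray(b, dtype=float)) + lp
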