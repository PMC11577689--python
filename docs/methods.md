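# Methods

## Model

Subjects are followed continuously on a finite state space `{0, ..., N}`
with a fixed set of permitted direct transitions forming a directed acyclic
graph (no state is revisited; at least one state is absorbing).  Subject i
carries a right-censoring time `C_i`, baseline covariates `w_i`, sparse
biomarker measurements `y_i1..y_in_i` at times `t_ij <= C_i`, and an
observed path `0 = T_0 < T_1 < ... < T_N_i <= C_i` through the graph.

The biomarker follows a Gaussian linear mixed model
`y_ij | b_i ~ N(X_i(t_ij)'beta + Z_i(t_ij)'b_i, sigma_e^2)` with
`b_i ~ N(0, Sigma_b)`.  Conditional on `b_i` the event process has
cause-specific intensities

    h_jk(t) = h0_jk(B(t)) * exp( w_i' gamma_jk + f(beta, b_i, t, alpha_jk) )

with `B(t) = t` (clock-forward, Markov) or `B(t) = t - entry time`
(clock-reset, semi-Markov; the timescale is uniform across transitions).
The two processes are assumed conditionally independent given `b_i`, so the
joint posterior factorises into the product of Gaussian longitudinal terms,
multistate event terms, the random-effects density and the priors.

Per subject, the multistate log-likelihood is the sum over sojourn
intervals of minus the cumulative intensity of every transition leaving the
occupied state, plus the log intensity of the realised transition at its
event time; the censored final sojourn contributes survival terms only.
Cumulative intensities are approximated by Gauss–Legendre quadrature with
15 nodes affinely mapped onto each sojourn interval (configurable; exact
for polynomial integrands of degree 29, and accurate to well below MCMC
noise for the smooth intensities used here — the only non-smooth case is a
Weibull shape < 1 evaluated from the state-entry instant, where the
integrand has an integrable singularity and accuracy degrades gracefully).

For unidirectional graphs the likelihood factorises exactly: the full
multistate term equals the sum over entered competing-risk blocks (all
direct exits from one state, treated as competing causes), and each block
term equals the sum of its cause-specific survival terms with competitors
censored at the block exit.  The test suite asserts both identities to
1e-10 on simulated cohorts.  This factorization is what makes the three
inference strategies target compatible posteriors:

* **JM-MSM** — one posterior over all parameters and all random effects;
* **JM-CR** — an independent posterior per competing-risk block, each
  conditioning on the block's risk set (subjects entering the initial
  state), the block event view, and a block-specific longitudinal index
  set;
* **JM-ST** — an independent posterior per permitted transition, reusing
  the parent block's risk set and index sets.

Blockwise longitudinal conditioning is *historical* (all measurements from
study start to block exit) or *concurrent* (only measurements strictly
after block entry and up to exit, falling back to historical for subjects
with none).  A measurement at exactly a transition time belongs to the
state being exited; the longitudinal design is always evaluated in study
time, also under clock-reset hazards.

## Baseline hazards

`WeibullBaseline` uses `h0(u) = shape * u^(shape-1) * scale`, i.e. the
scale multiplies outside rather than entering as `scale^shape`;
`weibull_standard_scale` converts to the textbook scale.
`BSplineLogBaseline` models `log h0` as a clamped cubic B-spline (default:
5 coefficients, boundary knots covering the observation window, one
interior knot; evaluation outside the boundary clamps to it).
`ProportionalBaseline` ties a transition to an anchor transition's spline
up to a free log-proportionality constant; the anchor map is user
configuration (the ten-transition preset anchors by target state).  When a
blockwise fit contains a proportional transition whose anchor lies outside
the block, the first such transition per anchor is promoted to a free
spline (initialised at the anchor's coefficients shifted by the log ratio)
and the rest re-anchor to it, keeping every block parameter identifiable.

## Priors

Defaults: `N(0, 100^2)` for beta, gamma and association parameters;
`N(0, 10^2)` for spline coefficients and log-proportionality constants;
`half-Cauchy(0, 1)` for Weibull shape and scale; `Inv-Gamma(0.01, 0.01)`
for `sigma_e^2`; `half-Cauchy(0, 2.5)` for random-effect standard
deviations and `LKJ(2)` for their correlation matrix, with an optional
`Beta(a, a)` prior on `(rho+1)/2` for the bivariate case.  On the
sampler's unconstrained scale the correlation matrix is parameterised by
canonical partial correlations; the vine construction (independent shifted
Beta distributions per CPC, shape `eta + (r - 1 - level)/2`) reproduces
the LKJ density exactly, which a unit test verifies in closed form for
r = 2.

## Posterior computation

The backend is an adaptive Metropolis-within-Gibbs sampler on the
unconstrained scale (log transforms for positive parameters, tanh for
partial correlations).  One sweep performs:

1. `beta` by independence Metropolis–Hastings from its exact conjugate LMM
   conditional given `(b, sigma_e^2)`; the Gaussian terms cancel
   analytically, so acceptance depends only on the event terms;
2. `sigma_e^2` by an exact conjugate inverse-gamma Gibbs draw (it enters
   the Gaussian terms only);
3. one adaptive random-walk block per transition, re-evaluating only that
   transition's event terms (the evaluator caches per-transition
   quadrature designs and per-subject partial sums);
4. the random-effects field by (a) a per-subject independence proposal
   from the conjugate Gaussian conditional given the longitudinal data,
   corrected for event terms in the acceptance ratio, and (b) a per-subject
   adaptive random walk;
5. a joint scale move per random-effect column, rescaling `(b_{.k}, sd_k)`
   together — the standardised effects are invariant, the Jacobian cancels
   the log-determinant, and the move traverses the ridge between `sd_k`
   and `sigma_e^2` that plain conditional updates cross only slowly;
6. the random-effects covariance (log sds + CPCs) by adaptive random walk
   against `sum_i log N(b_i; 0, Sigma_b)` only, which needs no likelihood
   evaluation.

Random-walk scales and covariances adapt by Robbins–Monro (decay
`t^-0.6`, targets 0.234 / 0.3 / 0.44) during burn-in only; proposals that
produce non-finite densities are rejected and counted.  Initialisation is
zeros on the unconstrained scale (random overdispersion optional), with
the random-effects field started at a conjugate conditional draw — a zero
field would let step 6 collapse `Sigma_b` before the data inform `b`.
Warm-up is phased: association parameters are held at zero for the first
half of burn-in while the random-effects field, variance components and
baselines settle, then released with freshly initialised proposal
covariances for the affected blocks.  Without this, fits with quadratic
associations occasionally spend thousands of sweeps in a transient where
alpha runs away before b is informed by the data.
Chains are deterministic given the seed; blockwise fits derive independent
per-block seeds from the master seed, so a block's draws are identical
whether it is fitted alone or alongside others.  Convergence is monitored
by split-chain R-hat (cross-checked against a reference implementation in
the tests); blockwise wall-time is reported as the maximum over blocks,
matching parallel dispatch.

Default draw and burn-in settings follow the package's own study sizes:
500–1000 retained draws, burn-in 2000–2500 for full-joint fits at n of a
few hundred and 1200–2000 for blockwise fits; the burn-in is always user
configurable and should be increased for larger cohorts.  Sparse
transitions (few events in a block) yield prior-dominated association
posteriors and are flagged in the logs.

## Model comparison

The leave-one-out unit is the *subject*: `D_i` bundles subject i's
longitudinal measurements (as indexed by the block's strategy — the
block-restricted vector under the concurrent strategy, consistent with the
block's conditioning data) and the block event outcome.  The pointwise
draws × subjects matrix is recorded during sampling and can be recomputed
from stored draws as a consistency check.  PSIS smoothing of the
importance ratios uses the standard generalised-Pareto tail recipe with
tail-shape diagnostics k-hat; k-hat > 0.7 triggers a warning, not a
failure — with many measurements per subject, subject-level LOO ratios are
heavy-tailed by nature and elpd differences should then be read
qualitatively.  Candidates on identical block data are ranked by elpd with
pairwise difference SEs from the paired pointwise values.

## Simulator

The generator draws covariates from a mixture of uniforms (defaults
U(18,65)/U(65,80)/U(80,90) with weights 0.55/0.30/0.15, standardised),
random effects from `N(0, Sigma_b)`, a censoring time (uniform or fixed),
then the path by iterated competing risks: from the current state, each
permitted exit's latent time solves `H_k(s, s+t) = -log U` by bracketed
Brent root finding (tolerance 1e-8) on the quadrature-based cumulative
intensity, capped at the censoring horizon; the earliest exit wins.  Visit
times are equidistant per epoch — the gap in force at a visit is the one
for the number of transitions observed by that time, the grid starts at 0
(configurable) and stops at the earlier of censoring and absorbing entry —
and measurements are `mu_i(t)` plus Gaussian noise.  Every simulated path
is re-validated against the graph.

Two presets fix the study conditions.  *Model 1*: five-state progressive
graph (8 transitions), clock-reset Weibull baselines, current-value
association, random-intercept/slope biomarker, `C_i ~ U(13, 24)`, visit
gaps (2.6, 2.0, 1.2).  *Model 2*: ten-transition graph, clock-forward
spline baselines with anchors (0,1), (0,3), (0,4) and proportional
others, a nonlinear-trend biomarker with bases `(1, (1+t)^-1.2 - 1, t)`
and r = 3 random effects, `C_i ~ U(4, 24)`, gap 1.  The presets' *true
parameter values are documented synthetic defaults* chosen to give
realistic event counts per transition at desk scale (they are not
estimates from any cohort); structural fields cannot be overridden,
numeric ones can.

What the simulator does not emulate: informative (outcome-dependent) visit
schedules, measurement error models other than additive Gaussian noise,
time-varying exogenous covariates, interval-censored transition times, and
reversible transitions.  Passing tests therefore demonstrate correctness
of the machinery under the stated generative model, not robustness to
those features of real cohort data.

## Verification scale and limits

The acceptance checks run at desk scale: one recovery replicate with
n = 400 subjects fitting all five approaches (posterior means of
association and covariate effects within ~4 posterior sds of truth, and
blockwise means within Monte-Carlo error of JM-MSM); credible-interval
coverage pooled over 3 replicates of n = 300 (binomial error band around
0.95 — at markedly smaller cohorts the frequentist coverage of Bayesian
intervals for fixed true values visibly departs from nominal, so n = 300
is the smallest size retained for this check); simulator checks at 10^4
paths; LOO against analytic brute-force refits on a 30-subject conjugate
toy; and quadratic-vs-linear association selection over 3 replicates of
n = 300 with a mean-centred stable marker, the regime in which the linear
and quadratic association terms are near-orthogonal and distinguishable
at this scale.  With 2 chains and the defaults above a
full acceptance run takes on the order of 15 minutes on one CPU.

Known limitations: a single sampler backend (no NUTS/HMC — gradients are
not implemented); one biomarker (no multivariate longitudinal submodel);
the Gaussian response only (the GLMM generalisation is an extension
point); no dynamic individual-level prediction; covariates are constant
within a block (block-entry-dependent covariates such as age at entry must
be precomputed by the caller per block); subjects need at least one
longitudinal measurement; and r (random-effects dimension) is in practice
small (presets use 2 and 3).
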