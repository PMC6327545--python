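# Methods

## Model

The observable unit is a *session*: one consultation producing an
ordered sequence of binary reassurance types (1 = cognitive,
0 = affective), with the duration of each reassurance, the patient's
binary response and its duration, and the clinician's ID recorded
alongside. A collection of sessions is modelled jointly under an
N-state hidden Markov model with Bernoulli emissions: latent state i
emits a cognitive reassurance with probability π_i, and the latent
chain moves according to a row-stochastic transition matrix Γ. The
likelihood of a session is the forward matrix product
δ P(x₁) Γ P(x₂) ··· Γ P(x_n) 1; sessions are assumed independent
(different patients, separated in time), so the joint log-likelihood is
the sum of the session log-likelihoods, with all sessions sharing one
parameter vector θ.

Assumptions worth keeping in view:

- first-order Markov dependence in the latent chain; observations are
  conditionally independent given states;
- parameters shared across sessions (relaxed only by the clinician
  fixed-effects variant);
- for homogeneous chains the process is taken to start in equilibrium,
  so δ is the stationary vector of Γ, computed by solving
  δ(I − Γ + U) = 1′; for N = 2 this equals
  (γ21, γ12)/(γ12 + γ21). Non-homogeneous (covariate-driven) chains
  have no stationary law, so δ₁ becomes a free parameter.

### Covariates and fixed effects

Off-diagonal transition probabilities can depend on lagged covariates
through the inverse logit: the transition *into* position t uses the
covariate vector z measured at position t − 1 (the previous patient
response type, and/or the natural log of the previous reassurance
duration, "log DOPR"). With this alignment every transition has a
covariate observation and nothing is needed before the first position;
the alternative — covariates at the current position — would either
discard the first transition or require an undefined pre-session value.
Covariates are not centred or standardised, so coefficients are
comparable with published estimates on the raw log-seconds scale.
Natural log is used for DOPR (only monotonicity matters to the link).

Clinician fixed effects duplicate the transition block (and the free
initial distribution, where estimated) per clinician; the session's
clinician ID selects the active set. Identical coefficient sets for
both clinicians reproduce the shared model exactly, which is tested.

### Special cases

- N = 1: independent Bernoulli observations (one parameter).
- Independent mixture: an HMM whose transition rows are identical, so
  states carry no memory. It is parameterised by one mixing weight plus
  the two emission probabilities (3 parameters for two components).
  Published comparison tables for this model family have been seen to
  imply a 4-parameter count for the mixture row — consistent with
  counting both transition entries separately — so the mixture row's
  printed-AIC identity is not used as an arithmetic anchor here.
- Fixed-effects baseline: with `initial="stationary"` each clinician's
  chain starts from its own stationary law (6 parameters); with
  `initial="estimated"` each clinician gets a free initial distribution
  (8 parameters). Both conventions are exposed because published
  parameter counts for this row imply the latter.

## Estimation

All probabilities map to an unconstrained working scale (logit for
scalar probabilities; multinomial logit with the diagonal as reference
for the rows of an N ≥ 3 transition matrix; identity for β). The map is
a bijection on the interior of the parameter space, round-tripping to
1e-10, so the optimiser is unconstrained. The joint negative
log-likelihood is minimised with BFGS (a quasi-Newton method of the
Newton type) with, by default, 10 random restarts — short pooled series
produce genuinely multimodal surfaces, typically with a collapsed
one-state ridge and occasionally boundary modes. Restart draws are on
the natural scale: π, γ, δ₁ uniform on (0.1, 0.9); β intercepts the
logit of a uniform (0.1, 0.9) draw, slopes uniform on (−1, 1).
`FitOptions.extra_starts` allows explicit warm starts;
`baseline_warm_start` embeds a fitted homogeneous baseline into a
covariate model (slopes zero), which guarantees the nested-model
likelihood ordering when fitting model families.

The forward pass rescales the state vector at each step and accumulates
log-constants, so validity does not depend on session length. The fit
itself evaluates a batched implementation that runs all sessions
simultaneously along the time axis (identical to the per-session
reference to machine precision, which is tested); this is what makes
the replicated simulation studies cheap. Label switching is resolved
after fitting by reordering states so π is ascending; probabilities
that saturate to exact 0/1 in floating point are pulled 1e-12 inside
the interval before repacking. Fits flag `boundary_pi` when an emission
probability is within ~0.001 of the boundary (typical of degenerate
data) and `large_beta` when |β| > 50, which signals a saturated, abrupt
transition profile whose scale is no longer interpretable.

### Confidence intervals

Standard errors come from the inverse of a finite-difference Hessian of
the negative log-likelihood at the optimum (pseudo-inverse with an
explicit warning when singular). 95% Wald intervals are formed on the
working scale and back-transformed: probability-type parameters get
asymmetric intervals strictly inside (0, 1); β intervals are symmetric.
Published interval tables for this model family show asymmetric π and δ
bounds, consistent with this construction, though the working-vs-natural
choice is not documented there; multinomial-logit block entries (N ≥ 3)
are reported on the working scale, as elementwise back-transformation is
not defined for them.

## Model selection and decoding

AIC = 2·nllk + 2p with p the length of θ, counted structurally from the
model specification (the identity AIC − 2·nllk − 2p = 0 is asserted on
every comparison row). `compare_models` derives one child seed per
candidate from the table seed, so identical candidates give identical
rows and the whole table is reproducible.

Viterbi decoding runs in log space; exact score ties are broken toward
the lower state index at each backtracking step, a deterministic
convention the decoder's tests pin down. Note that for 2-state
stationary chains, distinct maximising paths with exactly equal
probability are structural (detailed balance gives δ₁γ₁₂ = δ₂γ₂₁), so
oracle comparisons check the attained maximum rather than path
identity. Decoding after a fit uses the relabelled states, so state 1/2
keep their dominantly-affective/cognitive meaning.

## Synthetic data

The generator emulates the study's data shape: 44 sessions, lengths
drawn from the study's empirical frequency table (support 3–37; the
printed frequencies total 44 sessions and 480 reassurances against a
stated pooled 483 — the table is used as printed), clinicians assigned
50/50, and the latent chain at the published baseline estimates
π = (0.209, 0.782), γ12 = 0.265, γ21 = 0.169, whose stationary blend
Σ δ_i π_i = 0.559 reproduces the pooled 55.9% cognitive share.
Durations are log-normal per reassurance type with default locations
2.0 (cognitive) and 1.2 (affective) on the log-seconds scale and scale
0.8 — package defaults, not published values: the source reports only
that durations are heavily right-skewed with large outliers and that
cognitive reassurances last longer, which log-normality and these
locations reproduce (medians ≈ 7.4 s vs 3.3 s). Patient responses are
Bernoulli with probability 0.5 by default, optionally state-dependent.
When the generating model has covariate-driven transitions the
simulation closes the feedback loop: step t's transition matrix is
computed from the covariates simulated at t − 1 before the state is
drawn.

True latent states are returned only on request
(`return_states=True`) and are never written into session objects or
the exported CSV, mirroring real data; the recovery and decoding
oracles use them.

What passing tests on this generator do *not* show about real data:
between-session dependence (assumed absent), coding errors or coder
disagreement in the cognitive/affective labels, any dependence of the
response process on the reassurance content, and duration distributions
beyond the log-normal family.

## Numerical choices

- Row-stochasticity and stationarity tolerance: 1e-10
  (`STOCHASTIC_TOL`); pack/unpack round-trip tolerance 1e-10.
- Inverse logit evaluated via `scipy.special.expit`, which saturates
  cleanly, so |β′z| in the hundreds (as published fixed-state estimates
  are) cannot overflow and rows still sum to one exactly.
- BFGS gradient-norm target 1e-6 (numerical gradients limit what is
  attainable; convergence is accepted below 1e-3 with the attained norm
  reported), maximum 500 iterations per restart.
- Sessions of length 1–2 are accepted (the study's minimum is 3, but
  the likelihood is well-defined down to length 1).
- Degenerate collections (all observations identical) converge to
  boundary-adjacent π and are flagged rather than rejected.

## Problem sizes in the replicated checks

The acceptance script and the heavier tests use: 300 sessions × length
20 for parameter recovery (≈6000 observations, where every baseline
parameter is typically recovered within ±0.05; the π₁ sampling SD at
this size is ≈0.035, so occasional draws exceed 0.05); 20 replicates of
150 × 15 for AIC model recovery; 200 replicates of 100 × 20 with 3
optimiser restarts for interval coverage; 200 random instances for each
enumeration oracle; 1000 random matrices for stationarity. These sizes
are the package's chosen trade-off between Monte-Carlo error and
turnaround.

## Known limitations

- Wald intervals rely on asymptotic normality on the working scale;
  with few transitions per state they measurably undercover (the
  replicated coverage check for π₁ lands around 90–93% against a
  nominal 95%, and increasing the number of optimiser restarts does not
  move it, so this is a property of the interval construction, not of
  the optimisation) and they are unreliable near boundary modes
  (flagged).
- Covariate-driven transitions are implemented for two states only;
  N ≥ 3 supports homogeneous (optionally fixed-effects) chains.
- No EM/Baum–Welch, forward–backward smoothing, bootstrap intervals, or
  formal tests on β; model comparison is AIC only.
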