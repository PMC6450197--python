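# Methods

This note records the statistical model the package implements, the
design of the simulation laboratory, the numerical choices, and what the
shipped tests do and do not establish.

## Rating engines

**Standard ERS (baseline).**  A scalar ability θ̂ on the Rasch scale,
predicting `P = logistic(θ̂ − β_j)` and updating `θ̂ ← θ̂ + K(t)(Y − P)`.
Item difficulties are treated as known (from a calibrated bank) and are
not updated; the classic symmetric item-side update
`β̂_j ← β̂_j − K(Y − P)` is available behind `update_difficulty` but off in
every shipped experiment.  Keeping β known makes the baseline as strong
as possible: its predictions retain the full item-difficulty signal, and
any AUROC deficit relative to the multidimensional engine is attributable
purely to the unidimensional ability assumption.

**M-ERS.**  An M-vector θ̂ under the compensatory MIRT working model.
Only the dimensions an item indicates enter the logit, with working
slopes fixed at 1 (the engine accepts slopes for the natural extension,
but all experiments use 1, matching the design in which slopes are a
generating-model property, not knowledge available to the tracker).  The
per-dimension update weight `D_m` is 1 on indicated dimensions; for
non-indicated dimensions it defaults to 0 and is configurable in [0, 1]
(`d_weights_off`) — no analysis here uses spillover updates.

**Speed–accuracy (HSHS) engine.**  The trade-off score
`S = (2Y − 1)(d − T)` lives on `(−d, d)`.  We model it with the
exponential-tilted density `f(s|η) ∝ exp(ηs)`, the unique generative
model on that interval whose mean is the closed form

    E(S|η) = d·coth(ηd) − 1/η ,

and whose accuracy marginal `P(S > 0) = logistic(ηd)` coincides exactly
with the compensatory probability at `d = 1`.  Two useful consequences:
(a) sampling (Y, T, S) jointly from the score density is consistent in
distribution with sampling Y from the accuracy model (so the choice
between "joint" and "marginal" Study-3 generation, both implemented, is
immaterial in law); (b) `S − E(S)` is the exact score of the tilted
log-likelihood, so the HSHS update is the same stochastic-gradient step
as `Y − P` is for the Bernoulli model.

**Step size.**  `K(t) = k_max − (k_max − k_min)·min(t, h−1)/(h−1)`,
per-learner in the learner's own answered count t, defaults 0.4 → 0.1
over h = 200 occasions, clamped afterwards.  Larger early steps wash out
the arbitrary initialisation; the 0.1 floor keeps the tracker responsive
to (real-world) ability drift at the cost of a variance floor.

**Initialisation.**  θ̂(0) = 0, the origin of the scale.  With the
simulated population centred at μ = (1,1,1)′ this makes the
occasion-0 MSE equal to Var(θ) + 1 = 2 per dimension and the early bias
negative; both wash out within a few dozen items.

## Simulation laboratory

**Item banks.**  200 items, 3 dimensions, difficulty β ~ N(0, 1),
generating slopes α ~ U(0.5, 2) on loaded dimensions only.  `bank1`
(within-item multidimensionality): all items load on θ1, a 35% block
additionally on θ2, a disjoint 25% block additionally on θ3.  `bank2`
(between-item): disjoint 40/35/25% blocks load on exactly one dimension
each.  Block sizes come from a largest-remainder allocation, so the
40/35/25 proportions are met exactly at n = 200.  One bank per pattern is
shared across the correlation conditions of a run.

**Populations.**  250 learners, θ ~ N(μ, Σ) with μ = (1,1,1)′, unit
variances, and a common correlation ρ ∈ {0.0, 0.2, 0.5}.

**Sessions.**  Each learner receives an independent uniformly random
permutation of the full bank (200 items, each exactly once).  Because
item selection is non-adaptive, outcomes are independent of the engine's
state; sessions are therefore simulated as engine-free outcome streams
and scored through engines afterwards.  This factorisation is exact, lets
paired engines (standard vs M-ERS; accuracy vs HSHS) consume *identical*
outcome streams (common random numbers, so engine contrasts are paired),
and makes replaying a logged session through the streaming API reproduce
the logged predictions bit for bit.  Per-learner randomness descends from
spawned child seeds, so results do not depend on processing order.

**What the generator does not emulate.**  True abilities are constant
within a session (no learning during practice); there is no adaptive item
selection, no missingness, no response-time model beyond the tilted score
density, and the working model's slope-1 assumption is deliberately
misspecified relative to the U(0.5, 2) generating slopes.  Passing tests
therefore certify the tracking machinery under these stated conditions,
not performance on data with ability drift or calibration error in β.

## Evaluation

**AUROC.**  Rank (Mann–Whitney) statistic with ties counting ½,
identical to the trapezoidal area under the empirical ROC with
FPR = FP/(FP + TN); predictions are pooled over all learner–occasion
pairs within a condition (per-learner stratification is a trivial
variation on the returned arrays).  One-step-ahead semantics: every
prediction is recorded before its outcome.

**MSE and |bias| curves.**  At each occasion t, errors θ̂(t) − θ are
averaged over learners per dimension: MSE is the mean squared error,
|bias| the absolute mean signed error.  Study-3 style summaries report
both the **occasion-average** of these curves (the headline number — it
integrates start-up error and steady-state tracking noise over the whole
session) and the **final-occasion** value (steady state only).

**EAP benchmark.**  Posterior mean of θ under the slope-1 working
likelihood, known difficulties, and a standard-normal prior N(0, I),
computed by adaptive Gauss–Hermite quadrature: a Newton search finds each
learner's posterior mode (the problem is strictly concave), the Laplace
covariance scales and centres a 21-nodes-per-dimension product rule, and
the prior/kernel mismatch is reweighted exactly.  Adaptivity matters: a
200-item posterior has standard deviation ≈ 0.15, which non-adaptive
prior-anchored nodes (spacing ≈ 0.6) cannot resolve; the adaptive rule
matches dense-grid oracles to better than 1e-3 in the shipped tests.  The
independent N(0, I) prior is the conventional default and mirrors what
the online tracker knows: give the EAP the true generating prior
N(μ, Σ) instead (available via `prior_mean`/`prior_cov`) and it borrows
strength across correlated dimensions, which the per-dimension Elo
tracker cannot do, visibly lowering their agreement in the ρ = 0.5
conditions.

## Numerical choices

- Logistic evaluations route through `scipy.special.expit` / `logaddexp`
  (no overflow at extreme logits).
- `E(S|η)` uses the odd series `ηd²/3 − η³d⁴/45` for |ηd| < 1e-6
  (removable singularity at η = 0); the score sampler inverts the tilted
  CDF in a form stable for large |η| and reflects negative tilts with
  `u → 1 − u`, so it is an exact inverse CDF, monotone in u, with results
  clipped to [−d, d] against last-bit float spill.
- Largest-remainder ties break toward the lower-indexed dimension.
- Bank CSVs store reals at 17 significant digits and parse in
  round-trip mode, so write→read is exact.
- All experiment randomness descends from `SeedSequence(seed, spawn_key)`
  per (replication, pattern, condition); identical configurations produce
  byte-identical CSV output.

## Known limitations and observed behaviour

- Under slope misspecification the Elo fixed points are biased blends of
  the true dimensions; with U(0.5, 2) generating slopes the per-dimension
  |bias| of mean estimates is of order 0.1–0.5 depending on loading
  density, and the sharper HSHS likelihood converges more tightly onto
  those slightly-wrong fixed points.  Consequently the speed–accuracy
  engine clearly beats accuracy-only updating on sparsely-loaded
  dimensions (bank1 auxiliaries, bank2) but can be marginally worse on
  the densely-loaded primary dimension of bank1.  With matched
  (slope-1) generation the speed–accuracy advantage is uniform.
- The unidimensional baseline with known difficulties is far from random
  as a predictor (pooled AUROC ≈ 0.74–0.81 on three-dimensional data):
  the item-difficulty term alone carries substantial signal.  Its deficit
  relative to M-ERS (≈ 0.03–0.05 AUROC) is the cost of the
  unidimensionality assumption per se.
- Cold-start handling, ability drift, item-parameter learning during
  deployment, and information-based adaptive item selection are out of
  scope; the difficulty co-update exists only as a flag, and conjunctive
  (non-compensatory) prediction is not implemented.
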