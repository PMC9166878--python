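# Methods

## Model

`ciermix` fits a two-component latent response mixture to questionnaire
responses and response times (RTs). A binary indicator Δ_is per person ×
screen (item-level variant) or a probability π_i per person (screen-level
variant) selects between:

* **Attentive process** — generalized partial credit responses in the
  screen's trait, p(x=k) ∝ exp(Σ_{l≤k} (v·η − b_l)), and lognormal RTs
  with log-mean (β_C + β*) − τ − γ·|v·η − o| and log-SD σ_A. The distance
  term implements the distance–difficulty hypothesis: the farther the
  weighted trait sits from the middle step difficulty o, the faster the
  answer (factor exp(−γ) per unit).
* **Careless process** — category probabilities κ (free, content-free;
  the marginal over all careless patterns) and lognormal RTs with shared
  log-mean β_C and log-SD σ_C, independent of person and item.

Hierarchy: P(Δ_is = 1) = logistic(ψ_i − ι_s); person parameters
(ψ, τ, η_1..η_S) ~ MVN(0, Σ) with unit trait variances and zero means for
identification, Σ = diag(σ_ψ, σ_τ, 1, …) · Ω · diag(…). The screen-level
variant drops ψ, aggregates timing to mean seconds per item t̄_is, uses
screen-level offsets β*_s and the screen aggregates v̇ (geometric mean of
discriminations) and ȯ (arithmetic mean of middle step difficulties), and
mixes at the person level: π_i with prior Beta(λπ_P, λ(1−π_P)), π_P
uniform, λ half-Cauchy(0, 5).

Priors elsewhere: LKJ(1) on Ω; half-Cauchy(0, 5) on σ_ψ, σ_τ, σ_A, σ_C
and discriminations v; normal(0, 10) on step difficulties, β* (truncated
at 0), γ, β_C and the attentiveness difficulties ι (the prior list we
follow names all fixed-effect location parameters; ι is treated the same
way); Dirichlet(1) on κ.

Missing responses and RTs carry independent indicators and contribute a
factor of one; a fully missing person-screen has zero log-likelihood and
its posterior careless probability reproduces the prior.

## Estimation

No probabilistic-programming backend is available in the target
environment, so both fitters run a hand-written sampler in numpy with the
discrete indicator marginalized analytically (the stable log-sum-exp
two-component form). The base scheme is componentwise adaptive random-walk
Metropolis-within-Gibbs (Robbins–Monro scale adaptation during warmup
only, targets 0.44 scalar / 0.28 block), with person updates vectorized
across respondents (valid because persons are conditionally independent
given the shared parameters) and item updates batched: candidate
likelihood columns for all items are precomputed in a few vectorized
calls, then accepted sequentially so within-screen coupling through the
mixture stays exact.

Plain componentwise updates mix far too slowly for three structural
reasons, each addressed by a dedicated move:

1. **Scale–latent funnels** (σ_ψ with ψ, σ_τ with τ): coupled proposals
   rescale the latent column together with its SD; the standardized
   residuals are invariant, so prior and Jacobian cancel exactly and only
   the likelihood and the half-Cauchy prior enter the ratio.
2. **Location ridges** (β_C vs. all β* and vs. all τ): additive coupled
   shifts that leave the attentive RT means invariant, so only the
   careless RT density and priors respond.
3. **The weakly identified attentiveness hierarchy** (σ_ψ, the
   ψ-correlations, ι, and the ψ_i themselves): the correlation matrix is
   parameterized by canonical partial correlations with **ψ ordered
   last**, so the ψ-cpcs leave the data-rich (τ, η) block of Ω untouched;
   a block move perturbs ψ-cpcs or log σ_ψ, transports every ψ_i through
   its standardized conditional residual, and transports ι along the
   rate-preserving direction of the logistic-normal integral (probit
   approximation, scale 1.702) so that marginal careless rates are
   conserved; and ψ_i (and π_i in the screen model) are refreshed by an
   exact shrinkage-only slice sampler. The screen model additionally
   transports all π_i through Beta CDF/PPF quantile maps when (π_P, λ)
   move.

One recorded iteration performs several sweeps of the data-rich blocks
and many repetitions of the cheap hierarchy moves, tuned so all blocks
reach a comparable effective sample size per draw. Convergence is
assessed with split-R̂ over every stored scalar (including all person
parameters); the conventional 1.10 threshold flags the fit, never raises.

Posterior careless probabilities are mixture responsibilities computed per
retained draw — (1−p₁)C / (p₁A + (1−p₁)C) per person-screen, and the
analogous person-level quantity in the screen model — then averaged. The
reported careless **rate** is the posterior-mean responsibility (weighted
by items per screen for a response-level rate); a hard-threshold (0.5)
count is reported alongside as `hard_overall`, since either convention
appears in practice.

`marginal_cier_rate_for_screen` integrates 1 − logistic(ψ − ι) over the ψ
distribution by Gauss–Hermite quadrature (80 nodes); the simulator inverts
it by bisection to pick ι for a target population rate.

## Simulator: the stated world

Defaults resemble the empirical estimates the model class was developed
on: σ²_ψ = 1.98, σ²_τ = 0.11, trait correlation 0.43 (ψ–trait 0.24/0.17,
τ–trait −0.14/−0.06), γ = 0.04, β_C = 0.74 (≈ 2.10 s), σ²_C = 0.78;
design N = 300, two screens of 7 and 5 four-category items, target
careless rate 5%. Values without an empirical anchor were fixed once:
σ_A = 0.5 (a typical log-RT residual spread for single Likert items),
item parameters drawn per item (v ~ U(0.8, 1.6), step difficulties as an
ordered ±1 template around a U(−0.8, 0.8) center with small jitter,
β* ~ U(0, 0.7) spanning the empirically reported 0.00–0.68 range), and a
lognormal per-screen stem-reading time with median 8 s (log-SD 0.35) so
that TT and FRT are derivable — the reading-time component is pure
plumbing, not part of the measurement model.

Careless screens draw one of four patterns (equal mix by default):
uniform random; endpoint random (the two extreme categories with equal
probability); straight lining (one uniformly drawn category repeated);
diagonal lining (uniform start, ascending with wraparound; descending
available). The pattern is drawn per careless person-screen — the weaker
assumption; person-fixed patterns are an option. Careless RTs are iid
lognormal(β_C, σ_C) regardless of pattern, so RT carries no pattern
information, matching the model's assumption.

What the generator does **not** emulate: answer-order effects (items are
answered in presentation order, so AAT and TTFRT coincide on complete
data by construction), respondent-varying speed trajectories,
partially-attentive screens, careless behavior correlated with content
beyond the ψ–trait correlations, or raw time-stamped log events. A green
recovery test therefore establishes that the fitters invert the model's
own data-generating process at realistic parameter values — not that the
model is robust to violations of its assumptions.

## Timing measures and trimming

From item RTs plus reading time: TT (reading + all item RTs), FRT
(reading + first item RT), TT/J, TTFRT = (TT − FRT)/(J − 1), and AAT =
mean item RT excluding the first answered item (whose RT is confounded
with stem reading when reconstructed from log events). On complete data
TTFRT = AAT exactly. Trimming sets RTs above a threshold (default 90 s)
to missing, applies to item RTs, AAT and TTFRT but never to TT, and
reports counts so every N is auditable. The screen-level fitter is
aggregate-agnostic; `item_mean` (the plain mean of item RTs, no reading
time) is the cleanest choice when item RTs exist and is what the
aggregation-bias experiment uses.

## Indicator baselines

Long string (longest constant run; missing breaks runs), even–odd
consistency (per person: correlation between odd- and even-position
half-scores across scales — the one-sentence description in the
literature is under-specified; this interpretation over scale half-scores
is documented, not asserted against any published value), Mahalanobis
distance (sample covariance, n−1; χ²_p cutoff), and the sequential
multiple hurdle: RT threshold on a person-level timing measure (default
AAT; conservative 1 s, liberal 2 s) → long string (conservative: one
single run over all items; liberal: per-scale minimum runs, e.g. 5 of 7
and 4 of 5) → Mahalanobis on the survivors with the covariance
re-estimated after filtering (order matters and is preserved). Each
flagged person is attributed to exactly one hurdle. Missing responses are
handled listwise in the Mahalanobis step, with the exclusion count
reported.

## Numerical choices

* All mixtures in log space (log-sum-exp); logistic via `expit` /
  `log_expit`.
* GPCM probabilities as softmax of cumulative logits with max-shift.
* Middle step difficulty for K steps: middle element for odd K, mean of
  the two central elements for even K (reduces to o = b_2 for four
  categories).
* Constrained parameters sampled unconstrained with exact Jacobians:
  softmax simplex for κ, tanh canonical partial correlations for Ω
  (LKJ density expressed on the cpcs), log scales for SDs; β* by
  rejection at zero (prior mass zero below).
* Split-R̂ returns exactly 1.0 for bitwise-identical chains (they carry
  no between-chain information); otherwise the standard split
  Gelman–Rubin formula.
* Chains are initialized from cheap data-driven heuristics (centered
  person log-RT means, standardized screen scores) plus chain-specific
  jitter so R̂ retains diagnostic value.

## Scaling of the slow experiments

The recovery experiment (N = 300, 2 chains × 1000 iterations, ~2 min) is
run once in the test suite; the aggregation-bias experiment uses 3
replications at 2 × 800 iterations (~3 min) rather than a large
replication count, to keep the default test run inside its budget. With 3
replications the replication median is coarse; the tests therefore check
the documented *direction* (every replication's population careless rate
at or above the 5% truth) and a generous band around the documented
median bias, and judge trait-correlation unbiasedness by the median
signed deviation across replications.

## Known limitations

* The sampler trades generality for speed: the move set is tailored to
  this model's geometry; new model variants need new moves.
* Estimated careless rates at N = 300 sit slightly below the generating
  rate on some seeds (posterior-mean responsibilities shrink toward the
  prior when evidence is thin); the tolerance bands in the tests reflect
  this.
* The screen-level model attributes a partially careless person's noise
  screens to their traits when the person is classified attentive, which
  can attenuate single-dataset trait-correlation estimates at small N.
* Very long RTs are not modeled (both components are lognormal); the
  trimming rule exists precisely because such RTs are otherwise absorbed
  into the attentive component.
* Screens sharing one common K is a hard precondition; mixed response
  scales across screens are rejected rather than guessed at.
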