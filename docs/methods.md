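# Methods

## Scope and estimands

`occubound` estimates, for a region divided into `T` equal plots of which
`J` were each surveyed `K` times, (i) the occupancy rate of a rare
species under the knowledge that it is present somewhere in the region,
and (ii) an upper bound `N*` on the number of animals present. Two
occupancy estimands are tracked throughout:

* `gamma` — the Bernoulli parameter of the occupancy process;
* `x/T` — the **realized occupied fraction** of the finite plot
  population, `x = sum_j z_j`.

The realized fraction is the default reported quantity. Under the
presence conditioning it is supported on `{1/T, 2/T, ..., 1}`, so its
lower credible limit approaches `1/T` as the surveyed fraction grows with
zero detections — the behavior a finite-population reading of "proportion
of sites occupied" should have. `gamma`, in contrast, has full support on
(0, 1) and a strictly positive lower limit only through the conditioning.

## Conditional occupancy model

Priors: `gamma ~ Beta(a_g, b_g)` (default Uniform(0,1); configurable);
`q` — the probability of detecting at least one animal at an occupied
plot in one pass — carries either a point mass or a Beta prior. The joint
prior over `(gamma, z)` is restricted to `sum_j z_j >= 1` and
renormalized; because the indicator depends on `z` only, the conditional
updates of `gamma` and `q` are untouched by it and the model stays fully
conjugate.

The Gibbs sampler iterates:

1. sampled-plot occupancy: plots with a detection are occupied with
   probability 1; an all-zero plot is occupied with probability
   `gamma (1-q)^K / (gamma (1-q)^K + 1 - gamma)`. When the unsampled
   occupied count is zero the sampled vector is drawn conditioned on at
   least one success by a sequential scan (at position j, given all
   earlier entries are zero, the success probability is
   `r_j / P(>=1 success among j..J)`) — exact and O(J), no rejection
   loop;
2. unsampled occupied count: `x_u ~ Binomial(T-J, gamma)`, truncated to
   `>= 1` by inverse CDF when no sampled plot is occupied;
3. `gamma | x ~ Beta(a_g + x, b_g + T - x)`;
4. `q | z, y ~ Beta(a_q + s, b_q + K x_s - s)` with `s` the detections at
   occupied sampled plots (a prior refresh when none are occupied), so
   detection-prior uncertainty propagates into the occupancy posterior.
   Point-mass mode keeps `q` fixed, which the exact-reference tests use.

Degenerate inputs: a point mass `q = 1` with an all-zero history simply
forces those plots unoccupied; if additionally `J = T` (full census,
perfect detection, zero detections) the conditioning event has probability
zero and the fit raises an error rather than returning a sampler that can
never satisfy its constraint.

An independent reference, `brute_force_posterior`, computes the same
posterior exactly: for each point of a gamma grid (midpoint rule,
default 2001 nodes) the z-space sum is done in closed form — two-point
likelihood factors per sampled plot, a Poisson-binomial over the sampled
occupancy count convolved with a Binomial for the unsampled plots, the
all-unoccupied configuration removed. The test suite holds the sampler to
Kolmogorov distance < 0.01 against this oracle and both against a
test-local enumeration over all occupancy configurations at `T = 6`.

`k = max(1, floor(gamma_95U * T))` converts the upper occupancy limit
into an upper count of occupied plots. `gamma_95U` defaults to the 97.5%
quantile (upper end of the equal-tailed 95% interval); a one-sided 95%
quantile option exists. Floor-rounding with a floor of one plot encodes
assumed presence.

## Detection model and prior transfer

The reference-region model augments the latent `z_j` exactly and updates
the occurrence block `(a0, a1)` and detection block `(b0, b1)` by joint
random-walk Metropolis with Normal(0, 2.5) priors on the logit scale —
wide enough to be weakly informative, narrow enough to avoid probability
pileup at 0/1. Proposal scales adapt toward ~30% acceptance in batches of
50 during burn-in only, leaving the post-burn-in kernel fixed. Initial
values are prior draws, giving over-dispersed starts for the convergence
diagnostic. Zero-detection data raise an explicit unidentifiability error
pointing users to the conditional estimator; complete separation (all
detections in one visibility class) triggers a warning that the effect is
prior-dominated.

Occupancy is treated as closed within a plot across the K passes (the
passes are minutes apart in the motivating aerial design), so occurrence
is indexed per plot even though detection varies per plot-survey.

Prior transfer is deliberately decoupled from the training data:
`predict_q` applies the coefficient draws to an arbitrary target region's
visibility table, and `derive_q_prior` moment-matches the region-mean
draws to `Beta(m c, (1-m) c)` with `c = m(1-m)/v - 1`. Zero variance
yields a point mass; variance at or above the Beta bound `m(1-m)` falls
back to a point mass with a warning.

## Abundance model

Counts enter as a `(J, K)` matrix over plots known to be occupied
(all-zero rows are rejected as inconsistent with zero-truncation). A
single shared `lambda` is fitted by default — per-plot rates are not
identifiable at the sparsity this design produces. The latent abundance
is summed out exactly: the support runs from `max(1, max_t C_jt)` to the
smallest `n` where the zero-truncated Poisson tail beyond the largest
count is below 1e-10 at the largest admissible `lambda`, hard-capped at
`max(C) + 200`. The prior is Uniform(0, `lambda_max`) with
`lambda_max = 50` animals/plot, far above any plausible density for a
large slow-moving aquatic herbivore at ~1.3 km² plot size. A 1-D adaptive
random-walk Metropolis explores the marginal posterior; a dense grid
posterior over the same likelihood is the self-consistency reference.

Zero-truncated Poisson draws use exact inverse-CDF sampling on the
truncated support (uniform on `(e^-lambda, 1)` through the Poisson
quantile function), not rejection. `derive_upper_bound` draws, for each
`lambda` draw, `k` plot abundances and sums them; `draws_per_lambda`
controls how many Poisson replicates each posterior draw contributes.
Summaries are equal-tailed 2.5%/97.5% quantiles of the pooled draws.
Every draw is at least `k` by construction.

`(alpha, beta)` of the beta-binomial are configuration inputs; the
default pair (2.8, 2.2) gives mean individual detection 0.56, a
literature-supported aerial-survey value for this kind of animal, and is
never estimated from the target counts.

## Synthetic data

The generator produces exactly the structures the models assume:
Bernoulli occupancy across all `T` plots (optionally conditioned on
presence), a uniformly random sample of `J` plots, per-survey detection
that is scalar or logit-linked to binary strata/visibility covariates
(covariate frequencies default to 0.5/0.5; visibility per plot-survey by
default, per-plot optionally), zero-truncated Poisson abundance and
beta-binomial counts, with detections linked to counts
(`y = [C >= 1]`) when both exist. Conditioned occupancy vectors are drawn
exactly — a truncated-Binomial(T, gamma) occupied count by inverse CDF,
then a uniform choice of plots — rather than by rejection, so small
`gamma T` costs nothing.

What the generator does **not** emulate: spatial autocorrelation between
plots, habitat-driven covariate structure beyond the two binary
covariates, observer-specific detection (observers are pooled, as the
reader does for observer-level files), false-positive detections, and
movement between passes. Passing tests therefore demonstrate correctness
of the inference under the model's own assumptions, not robustness to
their violation in real surveys.

## Study conditions used by the reproduction script

`scripts/acceptance.py` uses: a 600-plot reference survey (K = 2,
occupancy truth invlogit-linked with a0 = 0.5, a1 = -1, detection
b0 = 0.4055 — i.e. q = 0.6 in good visibility — and b1 = -1, covariates
split 50/50); the three target regions at their design constants
(T = 1006/400/372, J = 133/40/37, K = 2) with all-zero histories; and a
300-plot reference count area at `lambda = 3` animals per occupied plot
with the default (2.8, 2.2) detection shapes. Chains: 3 per fit, 3000 to
6000 iterations each. These sizes keep the full script under a minute on
one core while leaving Monte-Carlo error well inside the tolerances the
tests assert.

## Numerical choices

* Midpoint-rule grids for the exact posteriors; CDFs at the nodes use
  `cumsum(w) - w/2`, removing the half-cell bias that a plain cumulative
  sum carries.
* Per-chain RNG streams derive from `(master seed, chain index)` via
  numpy's SeedSequence, so any chain can be rerun alone.
* `k` rounding adds 1e-9 before the floor to keep exact products (e.g.
  `0.1 * 50`) from falling to the lower integer through floating-point
  representation; at the magnitudes involved this cannot lift a genuinely
  smaller product.
* Bernoulli log-likelihoods use `log_expit` throughout; beta-binomial
  masses come from the log-beta form.
* R-hat uses the between/within variance form with a floor of 1;
  zero within-chain variance returns 1 for identical constant chains and
  +inf for disjoint ones. The convergence threshold is 1.1, checked on
  every fit and surfaced as a structured warning plus a `converged` flag,
  never silently.

## Known limitations

* The occupancy and detection stages assume closure within a plot across
  passes and no false positives; violations bias `q` and hence the
  occupancy upper limit.
* Transferring a detection prior between regions and years assumes the
  visibility covariate captures the relevant differences; residual
  region effects are not modeled.
* The abundance stage conditions on plots with at least one positive
  count; occupied plots where every count was zero are excluded by
  design, which slightly favors larger `lambda` at very low detection.
* `N*` is an upper-bound construction (it conditions on the upper
  credible count of occupied plots), not an abundance estimate; its
  interval should never be read as a population size CI.
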