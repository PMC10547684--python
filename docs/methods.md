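# Methods

This note documents the models, estimators and numerical choices behind
`phylossb`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one defensible option existed.

## Models and procedures

### Mk likelihood and ancestral states

Discrete characters evolve along branches as a continuous-time Markov chain
with generator Q (off-diagonal rates q_ij ≥ 0 in transitions/Myr, rows
summing to zero). The tree likelihood is computed by Felsenstein's pruning
recursion over all children of a node, so polytomies are handled natively.
Transition matrices P(t) = exp(Qt) are computed three ways by regime:

- k = 2: the closed form, with `expm1` for the off-diagonal terms so that
  short-branch probabilities do not lose precision to cancellation;
- k > 2 and μt ≤ 256 (μ = max exit rate): a uniformization series
  e^{−μt} Σ (μt)^n/n! R^n with R = I + Q/μ. All terms are non-negative, so
  genuinely tiny probabilities (a double transition on a short branch,
  ~(qt)², can be 1e−13 and smaller) come out positive. An eigendecomposition
  would bury them under its ~1e−16 absolute error and round them to zero,
  which turns into spurious −∞ log-likelihoods;
- k > 2 and μt > 256: eigendecomposition (with a scipy `expm` fallback when
  the generator is defective), where fast mixing keeps all entries far from
  the precision floor.

Partial likelihoods are rescaled at every internal node (log-scale
accumulator). Rescaling only below a threshold is not safe: the product of
two un-rescaled subtree maxima can jump below the subnormal range in a
single multiplication on trees of a few hundred tips.

Rates are fitted by bounded L-BFGS-B on log-rates (bounds 1e−8 to 1e3 per
Myr, tolerance 1e−8 on the log-likelihood) with random restarts (default 5),
because ARD likelihood surfaces are ridge-prone. A fit is *converged* when
its likelihood is finite; optimizer line-search complaints at the rate
bounds are recorded on the fit object rather than treated as fatal. The root
prior defaults to flat (1/k) and can be set to the stationary distribution
or a fixed vector; the choice matters little for the rate estimates but is
part of the reported reconstruction, so it is always carried on the fit.

Marginal ancestral probabilities use one inside (pruning) pass and one
outside pass propagating the root prior and sibling messages tipward; the
normalised product of inside and outside vectors is the exact marginal at
every node. This is algebraically equivalent to the re-rooting method but
costs two passes total instead of one per node.

Nodes are matched across ensemble trees by their descendant-tip set. The
across-tree z-test of a node's presence probability uses the s.e.m. of the
per-tree probabilities. That dispersion describes a derived quantity's
spread over the tree ensemble, not sampling noise of independent replicates
— the p-value is a heuristic inherited from the original procedure and
should be read as such.

### Fritz–Purvis D

Nodal values are estimated tips-to-root as the unweighted mean of daughter
values; d is the sum over all branches of |value difference across the
branch|. The random null permutes tip states; the Brownian null simulates a
unit-rate liability from a root value of 0 and assigns state 1 to the top m
liabilities, m being the observed count of 1s. Rank-thresholding (rather
than a fixed cutoff) preserves prevalence exactly in every simulation, which
is what makes the scaling D = (d_obs − d̄_B)/(d̄_R − d̄_B) calibrate to 1
under shuffling and 0 under the threshold model — a property the acceptance
suite verifies directly (300 tips, 50 replicate traits, 1000 nulls each,
both means within 0.1). Both a permutation p (share of shuffled d ≤ d_obs)
and a Brownian p (share of Brownian d ≥ d_obs) are reported; no normal
approximation is used. When the two null means coincide (degenerate data) D
is undefined and flagged rather than returned as a number.

### Correlated and directional evolution

A pair of binary traits is recoded as one 4-state character ((0,0), (0,1),
(1,0), (1,1)); simultaneous changes of both traits have rate 0, the standard
assumption. Four models constrain the eight single-change rates: independent
(each trait's rates ignore the other; 4 free), two directional models (one
trait's rates may depend on the other's state; 6 free each), and full
interdependence (8 free). Parameter counts follow the standard convention —
independence has the fewer parameters — which is also the convention
consistent with AIC = 2k − 2lnL bookkeeping on published model tables.

The correlation test is the LRT of independent vs interdependent (df = 4,
χ² reference). Its null calibration is checked by simulation: with traits
generated independently, the rejection rate at α = 0.05 stays inside the
binomial 95% interval and the empirical 95th percentile of the statistic
brackets the χ²₄ value of 9.49 (60 replicates on a 200-tip tree).

Model fits are warm-started in a sandwich order: independent → full
(seeded by the independent optimum) → directional models (seeded from both
the independent optimum and the full optimum collapsed onto each constraint
pattern), and the full model is re-polished if a directional model
numerically overtakes it. This guarantees monotone log-likelihoods across
nested models and fixes a practical failure mode where the 6-parameter
fits stall on likelihood ridges and the model comparison spuriously favours
the 8-parameter model.

Akaike weights are computed per tree and then summarised (mean ± s.e.m.)
across the ensemble, as are log-likelihoods and AICs. Ensemble sizes are
per-stage settings, not constants, because the directional machinery is an
order of magnitude more expensive than a single reconstruction.

### Stochastic mapping

Histories are sampled in the standard three steps: pruning pass; root state
from the root marginal; each child conditional on its parent and the data
beneath it (these draws are vectorised across all requested maps). Within-
branch paths conditioned on the endpoints are drawn by uniformization: the
jump count N from P(N=n) ∝ Poisson(μt)(n)·R^n[a,b], jump times as uniform
order statistics, the jump-state sequence as a discrete Markov bridge, and
virtual (self-) jumps discarded. Uniformization stays exact and cheap on
low-rate branches where forward rejection sampling stalls; its power table
is capped at R^4096 (the powers converge to the stationary projector, so the
last entry stands in for higher powers) and the jump-count loop at a
12-sigma Poisson tail. The path law is validated against an independent
fine-grid rejection simulator (χ² goodness of fit on event counts, 10,000
draws), and node-state frequencies across 2,000 maps agree with the
analytic marginals to < 0.03.

Rates are fixed at their ML estimates ("empirical" mapping); integrating
over rate uncertainty is out of scope.

### Node-age classification

For the observed trait, per-node presence probabilities come from an ARD fit
plus marginal reconstruction. The null reshuffles tip states across the tips
(default 100 reshuffles) and, by default, refits the rates on every
reshuffle — the null is "what would reconstructions look like if the trait
carried no phylogenetic information", and a reshuffled trait implies its own
(much faster) rate regime, so reusing the observed rates biases the null
toward the observed clumping. A fast mode that does reuse them is provided
and labelled approximate. Per node, the default bounds are the 2.5th/97.5th
percentiles of the null values (a min/max envelope is available as the more
conservative option): observed above the upper bound → present, below the
lower → absent, inside → equivocal. Calibration: reshuffled traits
themselves come out ≥ 90% equivocal; a trait painted onto one young clade
labels the clade's nodes present and yields a significantly younger
present-node mean age.

Present vs absent node ages are compared with a Welch (unequal-variance)
t-test. Nested nodes share descent and are not independent data points; no
correction is applied (deliberately mirroring the original procedure), so
the p-value overstates certainty and the means ± s.e.m. are the primary
output. A group with fewer than two nodes is reported not-testable instead
of raising.

### Phylogenetic logistic regression

The response is Bernoulli with mean p = logit⁻¹(Xβ); departures are
correlated across species with correlation exp(−α·d_ij), d_ij the patristic
distance in Myr — the Ornstein–Uhlenbeck-type structure of Ives–Garland
models, with independence recovered as α → ∞. Given α, β solves the GEE
estimating equation X'A V⁻¹(y−p) = 0 (V = A^{1/2} C A^{1/2}) by damped
Fisher scoring with a small ridge (1e−5) that keeps separated fits finite;
α is profiled on a log grid over [−8, 8] (refined by bounded scalar
minimisation) against the Gaussian working likelihood of the standardised
residuals. On a star phylogeny the estimates agree with ordinary logistic
regression to < 1e−4, the designed collapse.

Separation is flagged when a coefficient exceeds 8 on the logit scale or a
fitted linear predictor exceeds 15 — magnitudes no well-conditioned binary
regression produces — and the (finite, ridge-penalized) estimates are
returned with the flag.

Confidence intervals and p-values come from a parametric bootstrap (default
100 refits): responses are re-simulated by a Gaussian copula with the fitted
marginals and fitted correlation structure, and refit with α held at its
estimate (re-profiling α per replicate roughly triples the cost and moved no
conclusion in calibration runs). Observation weights multiply each species'
likelihood contribution (variance ∝ 1/w in the working covariance). This
weighted penalized-likelihood estimator is a deliberate, documented stand-in
for fully Bayesian weighted mixed models: it preserves the intent —
up-/down-weighting species by research effort while accounting for
phylogeny — in a form that is testable at desk scale. Collinearity
diagnostics are Spearman rank correlations plus VIFs from auxiliary linear
regressions, with perfect collinearity reported capped at 1e6.

## The synthetic-data generator

`make_fixture_dataset` emulates the shape of a species-level mammalian
behaviour dataset:

- a Yule tree rescaled to a 150 Myr root (mammalian crown depth);
- sociality and sex-specific adulticide as binary Mk characters (defaults
  2/150 and 1.5/150 per Myr — a handful of expected changes per root-to-tip
  path, enough variation to fit without saturating);
- male and female SSB as Bernoulli draws with logit p = b0 + 1.2·sociality,
  where b0 is calibrated by bisection so the *union* (either sex) hits the
  target prevalence (default 4%, the reported rarity of SSB in mammals).
  The two sexes share a latent liability (copula weight 0.7), so SSB
  co-occurs in both sexes far more often than at random. By default the
  residual copula is independent across species: SSB's phylogenetic
  clustering then enters only through conserved sociality, which keeps the
  SSB-positive count exactly binomial (a property the tests rely on);
  `ssb_phylo_weight` mixes in a Brownian liability when explicitly clumped
  residuals are wanted;
- captivity-only observation flags on ~20% of SSB-positive species (the
  approximate share of captivity-only records in published compilations),
  log-normal citation counts (median ~200, heavy tail), and a
  multi-year/site study flag more likely for heavily cited species.

Character simulation is exact Gillespie event sampling, so every dataset
carries its true histories; generators record the parameters, intercepts and
latent logits needed by the recovery tests. All randomness flows from a
single seed.

What it does **not** emulate: real mammal taxonomy or supertree shape,
correlated measurement error between traits, citation counts that depend on
the trait itself, or body-size covariates. Passing tests therefore
demonstrate that the estimators are correct and calibrated under their
assumed generating models at realistic sizes — not that those models capture
every feature of the real compilation.

## Problem sizes and test design

The validation suite runs at deliberately chosen desk scales: D calibration
on 300 tips with 50 replicate traits and 1000 nulls; LRT null calibration
with 60 replicates on 200 tips; Mk rate recovery on 400 tips (true rates
0.1/0.05 on a 30 Myr tree, median relative error well under 50%);
logistic-coefficient recovery on 600 tips over 20 seeds (median within
[0.8, 1.6] for a true 1.2); directional model recovery on 500 tips over 20
replicates (a 10× dependent gain rate is selected by Akaike weight ≥ 80% of
the time); 2,000 stochastic maps on 50 tips; node-age calibration with 100
reshuffles (full refit) on 200 tips over 20 replicates. Exact enumeration
over internal-state assignments on trees of up to 5 tips serves as the
likelihood oracle, and a time-discretized rejection simulator as the path-
law oracle; both oracles live in the test suite and share no code with the
implementation under test.

## Known limitations

- The node-age t-test inherits the non-independence of nested nodes
  (documented above); treat its p-values qualitatively.
- The across-tree z-test treats ensemble spread as a standard error.
- The phylogenetic logistic model estimates a single α for all species and
  assumes the exp(−α·d) correlation form; weights are a likelihood device,
  not a full measurement-error model.
- Stochastic mapping conditions on point estimates of the rates.
- No trait-dependent diversification models, no hidden-rate models, no
  joint (MAP) ancestral reconstruction, and no tree dating — dated trees are
  an input, not an output.
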