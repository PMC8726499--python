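# Methods

## Model

`phylorates` fits a Bayesian phylogenetic regression with heterogeneous
evolutionary rates. For `n` species on a rooted, strictly bifurcating,
time-calibrated tree, the response (a log10-scale continuous trait) is

    y = X β + e,       e ~ MVN(0, σ_b² · V(λ, r))

where `X` is a design matrix (intercept, continuous covariates such as
log10 body size and the trade-off partner trait, and binary predictors
such as parental-care forms and offspring habitat), and the residual
covariance is built from the tree:

* every branch length is multiplied by its **effective rate scalar** — the
  product of a single-branch scalar placed on it (if any) and all
  whole-clade scalars placed on ancestors whose clade covers it; a branch
  covered by no placement has effective scalar exactly 1;
* `V[i, j]` is the shared root-to-MRCA path length of tips `i` and `j` on
  the stretched tree, off-diagonals multiplied by **Pagel's λ ∈ [0, 1]**
  (diagonals, the root-to-tip depths, untouched);
* `σ_b²` is the **background rate**: the Brownian variance per unit branch
  length shared by all branches before scalar adjustment.

A whole-clade placement covers the clade's stem branch as well as every
branch below it; consequently a clade placement on a tip is the same
object as a single-branch placement there, and tip placements are stored
once, as branch placements. No placement of either kind is allowed at the
root: a root clade scalar would multiply every branch and is exactly
confounded with `σ_b²` (see the scale-identifiability invariant in the
test suite).

The model is a strict generalization of constant-rate PGLS: with no
scalars and λ = 1 it reduces to the familiar Brownian regression, which
is how the package's estimates are validated against analytic generalized
least squares.

## Priors

| parameter | prior | default | notes |
| --- | --- | --- | --- |
| each β_j | uniform(−100, 100) | fixed | diffuse on log10 trait scales |
| λ | uniform(0, 1) | fixed | |
| scalar value r | gamma(α = 1.1, scale solved so the median is 1) | fixed shape | increases and decreases equally likely a priori |
| log σ_b² | uniform(−20, 20) | configurable | the literature leaves this prior unstated; a broad flat prior on the log keeps the posterior scale-free |
| number of scalars k | uniform on {0, …, k_max} | k_max = all legal locations | locations uniform among size-k subsets, values i.i.d. gamma |

The gamma scale is found by root-finding the regularized incomplete gamma
function so that CDF(1) = 1/2 to below 1e-10. Legal scalar locations are
the `2n − 2` non-root branches plus the `n − 2` non-root internal nodes as
whole clades (`3n − 4` in total).

## Sampling

A reversible-jump Metropolis–Hastings sampler with single-move sweeps:

* random-walk updates of one coefficient at a time (cost O(np) thanks to
  a cached whitened design; only λ and scalar moves pay the O(n³/3)
  Cholesky refactorization);
* random walk on log σ_b²; random walk on λ with reflection at [0, 1];
* multiplicative random walk on an existing scalar's value (log-space
  proposal, Jacobian included);
* **birth**: a uniformly chosen unoccupied location receives a scalar
  drawn from its prior; **death**: a uniformly chosen scalar is removed.
  With the configuration prior above, the Green acceptance ratio reduces
  to the (tempered) likelihood ratio times the ratio of move
  probabilities, which differs from 1 only at the k = 0 / k = k_max
  boundaries, where unavailable moves are renormalized away;
* **exchange**: σ_b² → c·σ_b² and r → r/c for one random placement. The
  posterior has a ridge between the background rate and broad clade
  scalars (a clade scalar covering most of the tree is nearly
  likelihood-equivalent to a change of σ_b²); plain random walks cross
  this ridge very slowly, and the exchange move removes the resulting
  metastability. Scalar-block move weights are
  value/birth/death/exchange = 0.19/0.095/0.095/0.07, preserving the
  birth = death symmetry.

Proposal step sizes adapt by Robbins–Monro toward 0.3 acceptance during
burn-in only and are frozen afterwards, so the retained samples come from
a fixed-kernel chain. Chains initialize at the GLS estimates under λ = 1
with no scalars, λ at 0.5 (when free) and σ_b² at the GLS residual rate.
A fixed seed gives bit-identical output.

Retained samples store, besides the parameters, the per-branch effective
scalar vector **rebuilt from the placement set**. The incremental
log-rate bookkeeping used inside the chain accumulates float residues of
order 1e-16 across births and deaths; since the shift rule (below) pivots
on "exactly 1", those residues would otherwise corrupt it.

The shipped chain presets are `PAPER_SCALE` (200.5 million iterations,
500,000 burn-in, sampling every 100,000 — the published protocol) and
`DESK_SCALE` (20,000 / 2,000 / 10) for interactive work; every study in
the test suite states its own desk-scale dimensions explicitly.

ESS uses Geyer's initial-monotone-sequence estimator (FFT
autocovariances, adjacent pair sums truncated at the first non-positive
pair and forced non-increasing). On AR(1) chains it converges to
n(1−φ)/(1+φ); the test suite checks it against that closed form and
cross-checks against an independent implementation. Fits warn when any
monitored ESS falls below 1,000.

## Marginal likelihoods and effect sizes

Log evidence is estimated by stepping-stone sampling along power
posteriors π·L^t, reusing the same sampler with the likelihood tempered.
Powers follow Beta(0.3, 1) quantiles: with uniform(−100, 100) coefficient
priors, almost all of the prior-to-posterior contraction happens at very
small powers, and calibration against a closed-form evidence (fixed
covariance, uniform β priors — a Gaussian integral) showed the common
Beta(0.4, 1) ladder leaves too much of it inside the first stone. At 32
stones the estimate lands within ~0.3 log units of the closed form on the
30-tip benchmark.

A predictor's **effect size** is the drop in the median of replicate
log-evidence estimates (3 replicates by default) when it alone is removed
from the reduced model. For a binary predictor on a log10 response the
fitted coefficient also translates to a percentage change in the
response, present versus absent: `(10^β − 1) × 100`. Because the model is
linear in log space, all other covariates cancel in this contrast — the
"species of average size" framing is satisfied identically.

## Significance and model reduction

Px is the fraction of a coefficient's posterior on the minority side of
zero (ties counted on both sides, capped at 1/2; for continuous samples
the tie convention is measure-zero). A predictor is significant when
Px < 0.05. Backward elimination removes the single least significant
predictor (largest Px; ties broken toward the smaller absolute median
coefficient, keeping the audit trail deterministic), refits, and stops
when every remaining predictor is significant. One predictor is removed
per refit; the full per-step significance tables are retained.

Multicollinearity is screened with VIFs from ordinary (non-phylogenetic)
regressions of each predictor on all the others plus an intercept, with
flags at 5 and 10; perfect collinearity is reported, not raised.

## Rate shifts and attribution

A branch shows an **exceptional rate shift** when its effective scalar
exceeds 1 (positive shift) or stays below 1 (negative) in at least 95% of
posterior samples; a branch with no covering placement contributes
exactly 1 and counts on neither side. Reports carry the posterior
fractions, the median effective scalar and the branch's descendant tips.

Attribution compares a **simple model** (allometry and the trade-off
partner only) with the **reduced model** (significant predictors
included) on the same tree: branches flagged by the simple model but not
the reduced one are "explained" by the added predictors. Branch identity
across the two independently fitted models is the descendant tip set.
When the simple model flags nothing the percentage explained is reported
as undefined rather than zero.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with every draw reproducible from one seed:

* **trees** — pure-birth (optionally birth–death) simulations, tip edges
  extended by the waiting time to the next speciation so the final
  n-lineage period has positive duration, scaled to unit mean depth;
* **binary predictors** — a two-state Markov process from an absent root
  state (care and terrestrial reproduction are derived states in
  amphibians), columns resampled within a bounded retry budget until more
  than `min_present` (default 5) species carry the trait; clustering of
  presences arises from shared history, not from any constraint;
* **continuous traits** — `Xβ` plus an MVN residual with the
  λ-transformed, scalar-stretched covariance; continuous covariates are
  plain Brownian traits. The trade-off is induced by including the
  partner trait as a covariate with negative β — exactly what the
  inference assumes — not by a bivariate process.

Default study conditions, chosen once as realistic for log10-scale
comparative morphology: σ_b² = 0.02 (phylogenetic residual s.d. ≈ 0.14
per unit tree depth), λ = 0.9 where phylogenetic signal is estimated and
1.0 where a planted scalar is itself the object of study, body-size
Brownian variance 0.1 around a root value of 1.5 log10 mm.

Shipped presets:

* `small` — 50 tips, body size + one binary care predictor
  (β = 0.6, 0.25);
* `recovery` — 100 tips, three binary predictors with true effects 0.2, 0
  and −0.3 and ≥ 10 present species each;
* `shift-attribution` — 100 tips; one binary predictor present exactly in
  one clade, with a planted 8× scalar on that clade's stem branch and a
  large predictor effect (β = 1.2) generating the rate shift. Two design
  constraints matter and were fixed by a pilot design analysis: the clade
  must sit on a long stem (among clades holding 10–30% of the tips the
  picker takes the longest stem — a near-zero-length stem cannot express
  any stem-rate excess), and the predictor-driven jump must dominate
  stem-level Brownian noise, otherwise the realized residual can cancel
  it;
* `paper-shape` — 805 tips, body size, a trade-off partner trait and 13
  binary predictors with amphibian-like prevalences (care forms ~1–10% of
  species, terrestrial eggs ~30%, direct development ~15%), accepted
  within ±15% of their targets.

What passing these synthetic studies does **not** show: robustness to the
noise structure of curated literature data (midpoint merging, measurement
error, taxonomic mismatches), to tree misspecification, or to residual
processes outside the Brownian family (no Ornstein–Uhlenbeck or
early-burst alternatives are implemented). The generator draws from the
model the sampler fits, so the studies measure correctness and power of
the machinery, not model adequacy for any real dataset.

## Validation studies

`phylorates.validation` packages the correctness studies the test suite
asserts (and `scripts/acceptance.py` re-measures), each against an
independent reference:

1. the production likelihood against a brute-force dense multivariate
   normal with the covariance assembled by walking parent pointers (200
   random 5-tip trees and states, agreement to 1e-8);
2. posterior coefficient means of the constant-rate reduction against
   analytic GLS on the `small` preset (within 3 Monte Carlo s.e.);
3. a prior-only chain (likelihood power 0) against the analytic priors,
   including the uniform distribution over the number of scalars;
4. the 32-stone stepping-stone estimate against the closed-form evidence
   (within 0.5 log units);
5. 95% HPD coverage (target 90–100%) and sign recovery (≥ 90%) of true
   coefficients over 50 `recovery` replicates, with σ_b² and λ fixed at
   their known generating values (the stated study condition);
6. planted-shift detection and simple-versus-reduced attribution over 20
   `shift-attribution` replicates (each ≥ 80% of replicates), with the
   full reversible-jump machinery free in both fits;
7. the closed formulas (percentage change, Px counting, VIF).

Problem sizes (5–100 tips, chains of 12–120 thousand iterations, 20–50
replicates) are the package's desk-scale defaults; the published protocol
is preserved as the `PAPER_SCALE` preset and the same code paths scale to
805-species designs, which the `paper-shape` preset exercises at the
generation stage.

## Numerical choices and edge cases

* Dense Cholesky everywhere; no pruning-algorithm backend (at n ≈ 800 a
  factorization is ~20 ms, and the dense route is the one the oracle can
  check exactly).
* The λ transform scales off-diagonals only; λ = 0 on an ultrametric tree
  reproduces the i.i.d. regression exactly.
* Effective rates compose multiplicatively across overlapping placements
  (the only composition consistent with the stretch metaphor).
* The root stem, if present in an input file, is parsed and ignored for
  covariance purposes.
* Pruning collapses degree-2 nodes by summing incident branch lengths and
  preserves patristic distances among retained tips.
* Species joins are exact after whitespace trimming and space/underscore
  normalization; there is no fuzzy matching — a silent mis-join is worse
  than a reported drop.
* Degenerate inputs fail loudly: polytomies, non-positive or missing
  branch lengths, duplicate tips or rows, non-binary predictor codes,
  missing values, non-finite responses, non-positive-definite
  covariances, and perfectly collinear VIF inputs all produce specific
  errors (or flags, where the report is the right place for them).

## Known limitations

* Single-chain inference: convergence is assessed with ESS and traces,
  not with multi-chain diagnostics.
* The uniform prior over the number of scalars is permissive; under weak
  data the posterior carries a population of small, nearly neutral
  scalars. The 95% rule is deliberately conservative against this
  background, but negative-shift flags on quiet branches can appear and
  disappear between short chains — long chains (or the shipped
  paper-scale preset) are needed for stable branch-level inventories.
* Marginal-likelihood estimates carry Monte Carlo error of a few tenths
  of a log unit at desk scale; only signs and orderings of evidence
  changes should be interpreted, not absolute values.
* No measurement-error term, no OU/early-burst residuals, no model
  averaging, and no multiple-testing correction beyond the Px < 0.05 rule.
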