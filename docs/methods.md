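# Methods

## Model

A two-class naive-Bayes classifier over DNA words of fixed length *L*.
Class *c* ∈ {0 = background, 1 = foreground} has a position weight matrix
(PWM): independent multinomial distributions θ<sub>c,l</sub> over the
K = 4 nucleotides at each position *l* (the code is generic in K), plus
class probabilities *P*(*c*).  A word *x* is scored by the log joint ratio
log [*P*(fg) *P*(*x*|fg)] − log [*P*(bg) *P*(*x*|bg)]; the posterior
*P*(fg|*x*) is the logistic function of this score, and the decision rule
calls foreground at score > 0 with ties broken to background (the
conservative call in a rare-positive setting).

All simplex-constrained parameters are represented by unconstrained reals
through the softmax map θ<sub>a</sub> = e^{z_a}/Σ_b e^{z_b}.  This is
over-parameterized: adding a constant to all z of a group leaves θ
unchanged.  No gauge is fixed; every objective in the package is exactly
invariant along these flat directions, quasi-Newton ascent handles them
without difficulty, and identifiability is only ever needed at the θ
level, which is what all results report.

## The blended objective

Training maximizes

F(λ) = β₀ · log P(C|D, λ) + β₁ · log P(C, D|λ) + β₂ · log Q(λ|α),

with β on the probability simplex.  β = (0,1,0) is maximum likelihood,
(0,½,½) maximum a posteriori, (1,0,0) maximum conditional likelihood,
(½,0,½) maximum supervised posterior; the β₂ = 0 and β₂ = ½ edges are the
plain and penalized generative-discriminative trade-offs.  User-supplied
weights are renormalized to sum to one with exact zeros preserved, since
zeros select qualitatively different (closed-form) behaviour.

### Prior convention

The prior is a product of per-group Dirichlet-type densities *on the
unconstrained parameters*: including the change-of-variables correction,
each group contributes Σ_a α_a log θ_a − log Z(α) with
Z(α) = Π Γ(α_a+1) / Γ(Σα_a + K) — kernel exponent α_a, not α_a − 1.
This convention was chosen because it has two exact consequences that the
package's algebra relies on:

* **Power closure.** Q^ξ is again a member of the family with
  hyper-parameters ξα, exactly, up to a λ-independent normalization.
  Hence every point of the β₀- (or β₁-) axis is an MSP (MAP) fit with the
  prior at power ξ = β₂/β₀ (β₂/β₁), whose "virtual ESS" is ξ·ESS.
* **Conjugacy at the estimator level.** For β₀ = 0 the unique maximizer is
  θ = (β₁ n + β₂ α)/(β₁ N + β₂ ESS) per group — the pseudo-count
  estimator, recovering relative frequencies at β = (0,1,0).

Pseudo-counts are uniform ("uniform pseudo data"): column α = ESS_c/K,
with per-class defaults ESS_fg = 4 and ESS_bg = 1024; the class group
carries α = (ESS_bg, ESS_fg).  Whether the class probabilities should
carry their own prior mass is genuinely open; tying them to the per-class
ESS keeps a single strength parameter per class.

### Gradient and optimization

Every term of F is, per softmax group, of the form Σ_a w_a log θ_a
(+ const): w = observed counts for the joint term, posterior-expected
counts Σ_i P(c|x_i) for the conditional term's normalizer, and α for the
prior.  The gradient w.r.t. z_b is therefore always w_b − θ_b Σ_a w_a,
so per-group components sum to zero (the gauge direction) and the whole
gradient is assembled from count tables in O(N·L) per evaluation (the
posterior table is only needed when β₀ > 0).

Numerical training uses L-BFGS (scipy's implementation, memory 20) on the
per-observation objective F/N, so tolerances have a size-independent
meaning: convergence is declared at gradient max-norm ≤ 10⁻⁶ (of F/N) or
relative objective change ≤ 10⁻¹¹, with at most 1000 iterations.
Initialization is a smoothed generative warm start — the β₀ = 0 closed
form with weights (max(β₁, 10⁻³), max(β₂, 10⁻³)) — which is the natural
warm start for hybrid objectives and is already optimal at the generative
corners.  The conditional term is not log-concave in this
parameterization, so global optimality is not claimed; seeded multi-start
(`TrainConfig.n_starts`) is available and off by default.  Non-convergence
is reported via a flag, never an exception.  At the maximum-likelihood
corner with zero counts the optimum lies on the boundary (θ → 0); the
optimizer then stops on the objective-change criterion with θ below ~10⁻⁵,
which is immaterial at the θ accuracy the package targets.

## Evaluation protocol

Repeated stratified hold-out: in each round, floor(0.9·n) items of each
class train and the remainder tests (defaults: 1,000 rounds, 90%).  The
background is partitioned at the level of *chunks* (≤100 bp pieces), and
overlapping L-mers are extracted within each side, so near-duplicate
windows never straddle the train/test boundary; every test window counts
as one negative.  Each round r draws its partition from a seed derived
only from (protocol seed, r), which makes runs bit-reproducible and —
because the derivation ignores β — makes partitions identical across the
points of a simplex scan, so β comparisons are paired.

The headline measure is sensitivity at fixed specificity (default 99.9%):
with m negatives, k = floor((1−s)·m) false positives are allowed, the
threshold is the (k+1)-th largest negative score, and a positive counts
iff strictly above it (this equals the brute-force optimum over all
thresholds under the strict-inequality call convention).  Auxiliary
measures: ROC-AUC as the tie-corrected rank statistic, area under the
precision-recall curve by trapezoid (anchored at recall 0, precision 1),
and the classification rate at the natural threshold 0.  Summaries are
mean and standard error sd/√rounds (sd with one delta degree of freedom).

## Synthetic benchmark

Real TFBS collections cannot be redistributed, so the generator emulates
one: n_fg sites drawn column-wise from a ground-truth PWM, and an i.i.d.
(order-0) background emitted as chunks of ≤100 bp.  Defaults mirror a
typical small study: 104 sites of length 16 and ~68 kb of background.
The default motif has one dominant base per column at probability 0.7
(≈1 bit/position, typical of curated TF motifs); a uniform-column PWM
(strength 0.25) degenerates to the null case used for calibration tests.

The generator deliberately omits features of real data: compositional
heterogeneity and higher-order structure of genomic background, motif
occurrences hidden inside the "background" windows, strand ambiguity, and
ambiguous IUPAC symbols.  Passing tests therefore demonstrate correctness
of the estimator and protocol machinery — closed-form corner equivalence,
gradient exactness, logistic equivalence of the discriminative corner,
calibration of the sensitivity measure under the null — not that any β is
optimal for a particular real TF family, where background structure can
shift the useful region of the simplex.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the protocol at reduced
scale, chosen so the full pipeline (not a shortcut) is exercised: corner
comparisons on 104 sites + 12 kb background with 100 hold-out rounds, a
coarse β grid (step 0.25) at 50 rounds, parameter recovery at n = 10,000,
and null calibration with 400 uniform "sites" against 11 kb of uniform
background (the test size makes the expected null sensitivity ≈ 1/(m+1) ≈
0.1% at the 99.9% operating point).  All quantities are recomputed from
scratch at run time from the seed passed on the command line.

## Known limitations

* Two classes only; no Markov models of order ≥ 1, Bayesian networks, or
  Markov-random-field priors (the prior machinery here is the product-of-
  multinomials special case).
* Forward strand only; no reverse-complement scoring.
* No significance tests between β points beyond paired summaries; no
  genome-scale scanning with coordinate output.
* Scores are calibrated only through the built-in posterior identity;
  no isotonic/Platt-style recalibration.
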