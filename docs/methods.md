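# Methods

## The model

CAA treats the rows of one subject's standardized data block `X ∈ R^{n×m}`
as exchangeable samples and looks for pairs of sparse, support-disjoint unit
vectors `(u, v)` maximizing `uᵀXᵀXv`.  Unlike sparse PCA, which maximizes
retained variance along one axis, CAA maximizes *correlation between two
axes*: the solutions are 2-D projections in which two disjoint feature
subsets move together linearly.  Disjointness is what makes the
within-matrix problem non-trivial — without it the maximizer collapses to
`u = v` (the leading sparse principal axis).

We work with the sample correlation matrix `G = XᵀX/(n−1)` rather than the
raw cross-product.  The argmax is unchanged (the scale of `G` only rescales
the canonical value `d`), and `d` then lives on the correlation scale, which
keeps the ascent and orthogonality tolerances meaningful across problem
sizes.

### Solving one half-step exactly

With `v` fixed, maximizing `uᵀGv` under `‖u‖₂ ≤ 1`, `‖u‖₁ ≤ c₁` and the
(grouped) disjointness constraint is convex, and its KKT conditions give a
closed form: the solution is the L2-normalized weighted soft-threshold of
the gradient `g = Gv` with per-coordinate thresholds `θᵢ = λ₁wᵢ + λ₂`, where
`wᵢ = Σ_{j∈Sᵢ} |vⱼ|`.  Taking

    λ₁ = max over {i : wᵢ > 0} of |gᵢ| / wᵢ

is exactly the smallest multiplier that zeroes every coordinate whose
activation would violate the disjointness constraint (coordinates with
`wᵢ = 0` are untouched).  If the normalized thresholded gradient already
satisfies the L1 budget, `λ₂ = 0`; otherwise `λ₂` is found by bisection on
`[0, max|g|]`, exploiting that `‖s(λ₂)/‖s(λ₂)‖₂‖₁` decreases continuously
from its `λ₂ = 0` value to 1.  The bisection keeps the tightest *feasible*
iterate, so the returned vector satisfies `‖u‖₁ ≤ c` exactly and lands on
the budget to better than 1e-6.  Blocked coordinates are set to exact zeros,
so the disjointness constraint holds exactly, not to rounding.

A gradient whose admissible coordinates carry only rounding residue
(relative magnitude below 1e-12, which happens after deflation has removed
everything correlated with `v`) is treated as a degenerate step rather than
ground for a meaningless bisection.

### Alternation, initialization, restarts

Alternate convex search applies the half-step to `u` and `v` in turn; since
each half-step is an exact argmax, the objective is nondecreasing across
half-steps (the test suite enforces this with 1e-10 slack).  Convergence is
declared when the sup-norm change of the sign-canonicalized iterates falls
below `tol = 1e-6` (default `max_iter = 500`).  Sign canonicalization flips
`(u, v)` jointly so the largest-magnitude coordinate of `u` is positive;
`(−u, −v)` encodes the same correlation, and a canonical representative
stabilizes both the convergence check and the embedding metric.

Initialization needs care: a *dense* start vector is useless, because every
coordinate of `v` then carries positive disjointness weight and the first
half-step zeroes the entire gradient.  Restart 0 therefore starts from the
single coordinate with the largest loading in the leading eigenvector of
`G`; the remaining `n_restarts − 1` restarts start from random single
coordinates (seeded, without replacement).  A single-coordinate start lets
the first half-step sweep in that coordinate's strongest correlates and the
second half-step rebuild the partner block.  The best pair over restarts by
final `d` is kept.

### Sparsity budgets

Feasibility alongside `‖u‖₂ = 1` requires `1 ≤ c ≤ √m` (at `c = 1` the
solution is 1-sparse; at `√m` the L1 constraint is vacuous).  The default
`c₁ = c₂ = 1.75 ≈ √3` targets supports of about three features, matching
the block sizes of the default study; a uniform s-sparse unit vector has
`‖·‖₁ = √s`, so users expecting broader structures should raise the budget
toward `√s`.  Deliberately slack budgets are counterproductive here beyond
the usual loss of sparsity: surplus L1 mass is spent on noise coordinates,
and any noise coordinate captured by `u` is *blocked* for `v` in the next
half-step, which can lock the alternation into mixed-support local optima.

### Multiple pairs, retention, polynomial expansion

After a pair is accepted the gram matrix is deflated,
`G ← G − d(uvᵀ + vuᵀ)`, which makes the removed pair orthogonal to the
deflated gram (`uᵀG'v = 0` given unit norms and disjoint supports).
Extraction stops at `max_pairs`, on a degenerate step, or at the first pair
with projection `R² ≤ r2_min` (default 0.25); the sub-threshold pair is
discarded because deflating beyond noise-level structure is meaningless.
`R²` is always measured on the data (squared Pearson correlation of `Xu`
and `Xv`), not inferred from `d`.

Non-linear correlations are reached by appending re-standardized powers
`x², …, x^degree` of each column; the forbidden sets then place each
feature and all its powers in one mutual group so a feature can never be
"correlated" with its own transforms, which hold by construction.

## The embedding and its metric

Each retained pair is a point; a subject is the set of its points.  The
distance between canonical spaces is the chord distance
`‖u₁−u₂‖ + ‖v₁−v₂‖`, minimized over the 4-element group generated by the
axis swap `(u,v) ↦ (v,u)` and the joint sign flip `(u,v) ↦ (−u,−v)` — both
act by isometries, so the quotient remains a genuine metric on equivalence
classes of correlation structures (the suite checks symmetry, identity and
the triangle inequality on 1000 random triples).  Each chord term is at
most 2 for unit vectors, so distances are bounded by 4.  Neighbor queries
prune connections at distance ≥ 2.0 (default), which discards matches
whose axes share essentially no orientation; search is exact brute force —
cohorts here produce at most a few thousand points, and the vectorized
dot-product form handles that in milliseconds.

Subjects whose fits retain no pair are listed in the embedding's deferral
list, never silently dropped and never given a fabricated point.

## Classification and deferral

Each pair's vote is the mean label `q` of its up-to-`k` nearest labeled
neighbors inside the pruning radius (fewer, possibly zero, may exist;
a zero-neighbor vote is non-discriminative by definition).  Votes with
`|q − 0.5| ≤ t` are dropped and the subject score is
`Σ log(q̃/(1−q̃))` over the survivors, with `q̃` clipped to
`[ε, 1−ε]`, default `ε = 1/(2k)` — a Laplace-style stabilization that keeps
unanimous votes finite while preserving their ordering.  A subject with no
surviving vote is deferred, and a deferred subject never receives a
positive recommendation at any operating threshold.

`(k, t)` are tuned in an inner subject-stratified cross-validation loop:
the selection criterion is the mean inner-fold TPR under the FPR bound of
the deployment regime (default 0.025), with ties broken by pooled inner
AUC, then smaller `k`, then smaller `t`.  The default grid is
`k ∈ {1,3,5,7,9,15} × t ∈ {0, 0.05, …, 0.45}`; the harness and the
acceptance script run the reduced grid `k ∈ {1,3,5,9} × t ∈ {0,0.1,0.2,0.3}`,
which explores the same ranges at desk scale.

## Evaluation design

Folds are stratified at the *subject* level (all of a subject's
correlations stay together), and every method — CAE and the four baselines
(L1-regularized logistic regression and Euclidean k-nn, each on the
quartile-set featurization Q1/Q2/Q3 per feature and on the last recorded
row) — is evaluated on the identical fold plan for a paired comparison.
Baseline hyperparameters are tuned by inner-fold grid search on the
training subjects only.  Per-subject CAA fits are unsupervised and use only
that subject's own rows, so they are computed once and reused across folds;
embeddings and tuned `(k, t)` are rebuilt per outer fold from training
subjects only, and the leakage guard is asserted structurally.

ROC curves are empirical over all score thresholds; deferred subjects enter
ranking with a sentinel below every finite score.  Confidence intervals are
95% percentile intervals from a stratified subject-level bootstrap (1000
replicates by default); the choice of bootstrap (rather than fold-based
variance) is recorded in the output metadata.  TPR-at-FPR uses the
conservative convention — the largest TPR whose *empirical* FPR does not
exceed the target, with the strict decision rule `score > threshold` — since
the clinical tolerance is a bound, not a target.  "Quartiles" means the
three quartiles Q1/median/Q3 with the linear-interpolation convention.

## The synthetic cohort generator

The generator emulates the statistical object the method consumes — a
per-subject matrix of 1 Hz summary features over a two-hour epoch (default
7200×66, 40 subjects per outcome class) with sparse latent cross-feature
correlations — and deliberately not the clinical semantics of any real qEEG
feature, to which the method is agnostic.

Each planted structure draws its two feature blocks from a zero-mean
Gaussian with covariance `[[I, r·w_a w_bᵀ], [r·w_b w_aᵀ, I]]`,
`r = √target_R²`.  This construction was chosen over the more obvious
"both blocks load on one latent factor" because it is *identifiable*: every
feature has exactly unit marginal variance (so no class-separating
marginals exist unless explicitly requested), features are uncorrelated
within each block, the population canonical correlation between the blocks
is exactly `r` with canonical weights `(w_a, w_b)`, and the planted
partition is the unique argmax of the CAA objective.  A shared-latent
construction instead makes within-block correlation equal to cross-block
correlation, so *any* balanced split of the pooled features is an equally
good solution and "support recovery" is not even well defined.  The closed
form also means no noise-variance calibration loop: the population R²
equals the target exactly, and the realized empirical R² per subject is
recorded in the manifest.

The default study plants one structure shared by both classes
({0,1,2}↔{3,4,5}, R² = 0.8) and one carried only by class 1
({6,7,8}↔{9,10,11}, R² = 0.8): some correlation patterns are common, others
discriminative, which is precisely the situation the thresholded log-odds
aggregation is designed for.  Options exist for AR(1)-colored noise
(default off — the method treats rows as exchangeable) and for a class-1
mean shift used by the regime-contrast experiments, where the signal lives
in the marginals and the baselines, not CAE, should win.

What the generator does *not* emulate: heavy-tailed or bounded feature
distributions, nonstationarity within the epoch, missing data, temporal
trends in the correlation structures themselves, and outcome-label
censoring by treatment decisions.  Passing tests on these cohorts therefore
demonstrate the machinery — optimality of the solver, metric correctness,
leakage-free evaluation, calibrated generator — not clinical performance on
real recordings.

Support recovery is measured on the magnitude-thresholded support
`{i : |uᵢ| > 0.1·max|u|}`: when the L1 constraint is active the bisection
lands exactly on the budget, which necessarily retains a sliver of
near-zero noise coordinates; the relative threshold separates planted
loadings (≈0.58 for 3-feature blocks) from that residue (≲0.05) by an
order of magnitude.

## Problem sizes and determinism

The default study runs at its native scale (80 subjects × 7200 × 66); the
randomized solver sweeps and property tests use small matrices
(m ≤ 13, n ≤ 500) across many configurations, and the nested
cross-validation uses the reduced tuning grid above.  All randomness flows
from explicit seeds through named `SeedSequence` substreams: regenerating a
cohort from its manifest is bit-identical, and refitting with the same seed
reproduces model files byte for byte.

## Known limitations

- The alternating search is a local method for a biconvex problem; restarts
  mitigate but do not eliminate local optima, and very slack L1 budgets
  increase the risk (see the budget discussion above).
- Exactly tied gradient magnitudes make the minimizer of a half-step
  non-unique; ties are broken deterministically by coordinate order, but
  the reported pair is then one of several equivalent optima.
- The chord metric compares axes, not subspaces: two pairs spanning the
  same plane with rotated axes are distant by design (axes carry the
  feature attribution that makes structures interpretable).
- Deferred subjects are scored below every finite log-odds sum for ranking
  purposes; AUC on cohorts with many deferrals should be read together
  with the deferral rate.
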