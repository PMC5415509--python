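# Methods

This note documents the models and procedures implemented in `morphotrace`,
the defaults and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Parsimony character tracing

Characters are unordered, unpolarised, with at most four states (0–3).
Missing (`?`) and inapplicable (`–`) cells are coded apart in the data
model — the distinction documents *why* a cell is unscored under
hierarchical "c-coding" — but every computation treats both as "no
constraint on this tip". The tree is used as rooted and may contain
polytomies.

Step counts come from a unit-cost dynamic programme (a Sankoff recursion
with 0/1 costs), which is exact on polytomies and equivalent to Hartigan's
generalisation of Fitch's algorithm. Per-node MPR sets are obtained from
the same down-pass cost vectors combined with an up-pass that computes, for
each node and state, the cheapest completion of the rest of the tree; a
state belongs to a node's MPR set exactly when the two costs sum to the
global minimum. `brute_force_min_steps` validates this machinery by
exhaustive enumeration of internal-node assignments on small trees (only
observed states need enumerating, since assigning an unobserved state can
never reduce a unit-cost count).

ACCTRAN and DELTRAN are single-assignment resolutions built in
deterministic preorder. At each branch the child's admissible states are
those preserving global optimality given the parent's assigned state; when
"change here" and "change later" tie, ACCTRAN changes immediately (pushing
transformations rootward, favouring reversals) and DELTRAN defers
(favouring parallel gains near the tips). Remaining ties break toward the
smallest state label so runs are repeatable. Both resolutions are true
MPRs, so their change lists always have exactly the Fitch length.

**Within-clade step counts.** Step counts can be restricted to the clade
spanned by a set of terminals (`within=`). Tips outside the set impose no
constraint and contribute no steps. For a monophyletic set this equals the
count on the induced subtree, and it is the scope in which the package's
homoplasy comparison is posed (homoplasy *within* the radiation of
interest, not in distant outgroups).

**Synapomorphies.** A character marks a clade when ACCTRAN and DELTRAN both
place a change to the same derived state on the clade's stem branch. Before
placing changes, tips with no observed state for that character are pruned
(with degree-one nodes suppressed): an unscored tip adjacent to the stem
otherwise lets ACCTRAN drag the change one branch rootward at equal cost,
making the placement spuriously ambiguous. The `homoplasy_free` flag uses
the character-level criterion *s = m* — the character traces at its
conceivable minimum (consistency index 1), i.e. every derived state arises
once and nothing reverses. A character can therefore appear as a clade's
stem synapomorphy yet be flagged homoplasious when the same character
changes again elsewhere on the tree.

## Homoplasy indices and the class comparison

For each character the table reports observed steps *s*, the conceivable
minimum *m* (observed states − 1), and the star-tree maximum *g* (tips
observed minus the modal state's tally). Two consistency-index conventions
are reported side by side, because both circulate under the same name:
`ci_standard = m/s` (the textbook index) and `ci_paper = s/g`. The
retention index is `(g − s)/(g − m)`. Constant characters get undefined
(None) indices rather than 0/0.

The sexual vs non-reproductive comparison restricts to characters with at
least two observed states among the ingroup terminals, counts each
character's steps within the ingroup clade, and fits a Poisson GLM
(log link) of step count on character class. The GLM is fitted by IRLS
(convergence when the largest coefficient update is below 1e-10, at most
100 iterations) with Wald z inference; for a single binary factor the
fitted group means equal the observed group means exactly, which is the
closed-form oracle used in testing. Because the choice of reference level
flips the sign of the class term and changes what the intercept measures,
*both* codings are fitted and reported; the summary prints the per-class
step counts for boxplot-style display. On the packaged dataset the class
effect is |z| = 1.06 (p = 0.29) — no detectable difference in homoplasy
between sexual and non-reproductive characters — while the intercept is
positive under either coding (some homoplasy in both classes).

## Phylogenetic signal and ancestral states

A continuous trait y over the tips is modelled as multivariate normal with
mean μ·1 and covariance σ²·C(λ), where C is the Brownian-motion covariance
(shared root-to-MRCA path lengths; diagonal = tip depths) and C(λ) scales
the off-diagonal entries by λ ∈ [0, 1]. μ and σ² are profiled analytically
through a Cholesky whitening; λ is maximised by bounded Brent search
(tolerance 1e-8) with the endpoints λ = 0 and λ = 1 checked explicitly.
No λ > 1 extension is offered. Estimation expects a chronogram; a warning
is issued on clearly non-ultrametric trees.

Blomberg's K is the observed ratio of phylogenetically uncorrected to
GLS-corrected mean squared error, divided by its analytic Brownian
expectation `(tr(C) − n/(1'C⁻¹1))/(n − 1)`; K ≈ 1 under Brownian motion,
K < 1 when relatives resemble each other less than Brownian motion
predicts. An optional permutation test shuffles trait values over tips
(seed mandatory; add-one p-value).

Ancestral states for continuous traits are the maximum-likelihood (GLS)
estimates under Brownian motion, computed by solving the weighted-Laplacian
linear system that minimises Σ (Δ along branch)²/branch length with tips
clamped at their observations; the root estimate coincides with the GLS
phylogenetic mean. Zero-length branches are regularised to 1e-9 (the two
nodes effectively fuse).

## PGLS

GLS with residual covariance σ²·C(λ): `covariance="brownian"` fixes λ = 1,
`"lambda"` profiles λ by ML on the same bounded search, and an identity
covariance reduces exactly to OLS (tested against an independent
implementation). Categorical predictors expand into treatment dummies
(first level alphabetically as reference — the three-level region factor
becomes two dummies). Inference is Wald-t with n − p degrees of freedom;
σ̂² uses the n − p denominator while the reported log-likelihood is the ML
profile value. Rank-deficient designs are rejected naming the collinear
columns; species missing data are dropped and listed.

Copulatory-organ complexity is the count of accessory structures scored
present (state 1) among characters 37–44; unknown or inapplicable cells
count as absent, so the score tallies confirmed presences only. Responses
that can be zero (organ counts, complexity) are log-transformed as
log(x + 1) in the demonstration pipeline; the choice is exposed to the
user rather than hard-coded into the model.

## Latitudinal diversity gradient

Occurrence records are binned into half-open latitude bands
`[k·w, (k+1)·w)` anchored at the equator and mirrored south (default width
w = 10°); a species counts at most once per band, and empty bands between
occupied ones are kept so the profile tiles the observed range. The fit is
on (band midpoint, richness) pairs.

The 95th-percentile summary is a B-spline quantile regression: a clamped
basis of degree d with no interior knots (k = d + 1 functions, spanning the
degree-d polynomials) and coefficients minimising the pinball loss
Σ ρ_τ(y − Bc), solved as a linear programme (HiGHS), hence deterministic.
Degree is chosen from candidates 1–5 by AICc with the asymmetric-Laplace
quasi-log-likelihood `n·(log(τ(1−τ)) − 1 − log(mean pinball loss))`;
numerically zero-loss fits share an infinite quasi-likelihood so ties
resolve toward the smaller degree. This quasi-AICc is the convention of
the quantile-regression ecosystem, and it is *liberal*: at τ = 0.95 with a
dozen bands it not infrequently admits degree 4–5. The package treats the
fitted curve's argmax, not the degree, as the quantity of interest.

The diversity optimum is the argmax of the selected fit on a 0.1° grid
(flagged when it sits on the domain boundary). Its 95% CI is a percentile
bootstrap over (midpoint, richness) pairs with the degree held fixed at the
original choice; only resamples whose x-values are all identical are
skipped (and counted — more than 5% triggers a warning). Percentile CIs
for an argmax need not contain the point estimate by construction, so that
property is asserted statistically in tests, never per run. Longitude uses
the same operations with 40° bands.

## Synthetic data

All generators are pure functions of (parameters, seed); no global random
state is used or mutated.

* **Yule trees** — forward pure-birth simulation: with k lineages the wait
  to the next split is Exp(k·birth); a final Exp(n·birth) interval gives
  every tip a positive pendant edge. Trees are exactly ultrametric.
* **Mk characters** — jump-chain simulation root-to-tips: total leaving
  rate `rate` per unit branch length, uniform jumps among the other k − 1
  states, uniform root state.
* **Brownian traits** — one multivariate-normal draw with covariance
  σ²·C(λ) via Cholesky (jitter 1e-12 for the λ = 0 diagonal case).
* **Occurrences** — each species receives a range centre from
  Normal(peak, width) and `records_per_species` records scattered
  Normal(centre, jitter); longitudes are uniform noise. Defaults (55
  species, peak 20°, width 15°, 4 records each, 2° jitter) mirror the
  diversity-gradient study conditions the package targets.

What the generators do *not* emulate: spatial sampling bias and effort
gradients, range asymmetry and coastline geometry in occurrences;
among-character rate variation, ascertainment of variable characters, or
coding dependence (c-coding hierarchies) in discrete matrices; measurement
error in traits. Passing calibration tests on these generators shows the
estimators are correct under their own assumptions, not that real data
meet those assumptions.

## Packaged dataset caveats

The packaged *Pisione* dataset (26 terminals, 44 characters, combined
Bayesian topology, terminal coordinates) carries two caveats documented in
`data/FIXTURE_NOTES.txt`: the outgroup family order is only partially
resolved by the underlying analyses (the packaged resolution is the one
consistent with the published tracing, under which palp surface — character
1 — is homoplasious and buccal aciculae remain the sole clean *Pisione*
apomorphy), and the continuous trait table is a synthetic demonstration
stand-in except for its complexity column, which is computed from the real
matrix. Signal/PGLS runs on that table are demonstrations of the API, not
biological results; quantitative validation of those estimators is entirely
synthetic-data based. The packaged occurrence set holds only the 16
sequenced-terminal coordinates, so the gradient analysis on it is likewise
a demonstration.

## Problem sizes used in validation

The calibration suite uses 200-tip trees with 100 replicates per λ value
for λ recovery, a 100-tip tree with 500 replicates for K, 50-tip trees
with 100 replicates for the PGLS null, 200 random ≤ 6-tip instances for the
parsimony oracle, and 50 occurrence datasets with 500 bootstrap replicates
each for gradient recovery — sizes at which Monte-Carlo error is small
relative to the tolerances asserted while the whole suite stays quick on a
laptop.

## Known limitations

* Parsimony is unordered and unweighted only; no Wagner/Sankoff cost
  matrices, no likelihood reconstruction of discrete characters.
* The λ model offers no OU/EB alternatives and no λ for discrete traits.
* The original copulatory-organ regressions were fitted by MCMC; this
  package substitutes deterministic ML/GLS with the identical mean
  structure for reproducibility, so posterior-based uncertainty summaries
  are out of scope.
* ACCTRAN/DELTRAN tie-breaking (smallest state, preorder) is one of
  several defensible conventions; change lists are reproducible but not
  canonical across software.
* The quasi-AICc degree choice is liberal at extreme quantiles and small
  bin counts (see above); consumers should treat the selected degree as a
  smoothing choice, not an inference.
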