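# Methods

## Regular fractions and the generator search

A regular 2^(k−p) fraction is built from m = k − p basic columns (the full
2^m factorial in standard order) plus p generated columns, each the
elementwise product of a subset of basic columns. Writing the generator of
added factor g as the word w ∪ {g}, the defining contrast subgroup is the
closure of the p generator words under symmetric-difference products; every
word evaluates to a constant sign over the fraction (all +1 here — the
principal fraction). The minimum word length is the resolution. Two effects
are aliased exactly when their factor sets differ by a defining word, so the
alias table is computed purely combinatorially (cosets of the subgroup),
and is cross-checked in the tests against a brute-force comparison of
model-matrix columns for every fraction with k ≤ 6.

Generator sets are found by depth-first search over candidate basic-column
subsets of size ≥ resolution − 1, in increasing bitmask order, pruning any
partial assignment that creates a word shorter than the requested
resolution. All surviving assignments are scored by their word-length
pattern (A₃, A₄, …) and the lexicographically smallest pattern — minimum
aberration — wins, with ties broken by candidate order so construction is
deterministic. This reproduces the standard catalog designs (e.g. 32 runs
for 11 factors at resolution IV, 64 for 8 factors at resolution V, 128 for
11 at resolution V) without shipping a catalog; `min_runs_for_resolution`
simply walks run sizes upward until the search succeeds. A node budget
(5·10⁶) turns pathologically large searches (k > ~16) into a clean error.
Designs read from bare CSVs, lacking generator provenance, get their
subgroup recovered by exhaustive constant-product enumeration over the 2^k
effect masks (k ≤ 16), which also detects non-regular run subsets.

A projection onto a factor subset is a (replicated) full factorial iff the
subset contains no defining word; `assign_columns` exploits this to place
the four genetic factors on columns whose projection enumerates all 16
strains, searching column subsets in lexicographic order. Column sign flips
(`flip_columns`, `orient_fraction_towards`) move between the 2^p
statistically equivalent sign-variants of a fraction — same word lengths,
balance and alias structure — which is how a fraction can be oriented to
contain a particular reference corner.

## Effect model and inference

Responses are modelled at replicate level (each biological replicate is one
observation; this preserves error degrees of freedom rather than averaging
them away). The model matrix holds an intercept, the coded main-effect
columns, and optionally one two-factor-interaction column per alias class —
the lexicographically smallest pair representing its class, since members of
a class are indistinguishable by the data. Requesting two terms of the same
class is rejected before fitting. Fitting is ordinary least squares via
statsmodels (pseudo-inverse, i.e. orthogonal-decomposition based); rank is
decided at 10⁻¹⁰ × the largest singular value, and a rank-deficient matrix
raises an error naming the dependent columns. After removing runs (the
infeasible genotypes) some interaction representatives become collinear on
the survivors; `fit_design(drop_collinear=True)` drops those greedily in
term order and records them — main effects are never dropped.

Inference is per-coefficient two-sided t-tests with Bonferroni correction
over the m non-intercept terms of the fitted model (p_adj = min(1, m·p));
stars mark adjusted p ≤ 0.05 / 0.01 / 0.001. Screening significance is
judged on the ME+2FI model, whose residual is not inflated by unmodelled
interaction signal. Model quality is summarized by adjusted
R² = 1 − (1−R²)(n−1)/(n−q−1) with q non-intercept terms, and by the mean
absolute error in mg/L. For saturated or zero-variance fits these are
reported as NaN rather than extrapolated.

## Sequential campaign

Round 1 screens all k factors at resolution IV. Runs whose genotype cannot
be constructed are dropped, not imputed; the estimability report then gives
the rank of the intercept+ME matrix on the survivors and the column
correlations the removal introduced among main effects and among
interaction representatives. `fix_factors` pins the k_fix (default 3)
largest-|coefficient| significant main effects at the level given by their
coefficient sign — favorable for a maximized response — and refuses (with
the available count) if fewer are significant. Round 2 refines the
remaining factors at resolution V, fits the full ME+2FI model, and
enumerates every coded combination of the active factors (capped at 2²⁰),
breaking predicted-response ties toward the lexicographically smallest
settings. The optimum is probed three ways: a leave-out refit excluding the
top-producing run (is its setting still ranked first?), one-factor
perturbations (all deltas ≤ 0 by the argmax property; a zero delta marks an
inert factor), and 2×2 interaction cell means, whose contrast
(mean₊₊ + mean₋₋ − mean₊₋ − mean₋₊)/4 equals the fitted interaction
coefficient on balanced designs.

## Synthetic study generator

`default_pca_truth` encodes a hidden linear model over the eleven study
factors emulating a p-coumaric-acid production campaign. Its structure:
dominant positive main effect of PAL-C4H expression (+35 mg/L per coded
unit), strong negative buffering effect (−25), positive Phe supplementation
(+18); moderate effects for temperature (−16), agitation (+16), ARO4 (−16),
AROL (−14) and the remaining media/process factors (±12); positive
interactions T:ARO4, rpm:OD and AROL:ARO4 (+9 each); and synergies of the
media and genetic factors with the dominant factors (N:PAL-C4H −18,
Glu:Phe +18, ARO7:PAL-C4H +18, OD:Phe +8, T:PAL-C4H −8, rpm:PAL-C4H +8,
AROL:Phe −8) — e.g. nitrogen source and downstream-gene expression matter
most in high-flux strains, and Glu or a larger inoculum pay off when Phe is
supplemented. The intercept (147 mg/L) is calibrated so the noiseless
response spans 2 to 448 mg/L over the full 2¹¹ space — roughly two orders
of magnitude, as in the real campaign — while staying positive everywhere,
so the truth is exactly linear on the design region and recovery studies
measure the estimator, not a truncation artifact.

The magnitudes were chosen once, with two deliberate constraints. First,
the top three main effects are strictly PAL-C4H > pH > Phe, so the
canonical screen fixes those factors. Second, every factor left active
after fixing retains a decisive net effect at the optimum (|ME_eff| +
aligned interactions ≈ 20–34 mg/L, i.e. ~3σ of the corner-prediction
error under the default noise): with multiplicative noise the top of the
response surface is also its noisiest region, and interaction-coupled
factor blocks can flip jointly at little cost (block flips preserve their
internal interaction terms), so a truth with near-tied corners would make
the predicted optimum unstable no matter how well the model is estimated.
The folded synergies provide these margins in round 2 without perturbing
round-1 main-effect ranking (resolution IV keeps MEs clean of 2FIs).

Replicate noise is multiplicative log-normal with mean 1 and coefficient of
variation `noise_cv` (default 0.15): titres are positive and replicate
spread scales with the mean, which matches low- vs high-titre replicate
behaviour better than additive noise (available as an option, sd =
cv·mean). Responses are truncated below at `floor` (default 0; never active
under the default truth). Default replication is 3 for the screening round
and 2 for the refinement round. What the generator does not emulate: batch
or plate effects, growth dynamics, higher-order interactions, curvature
between the coded levels, or measurement-specific error structure — so a
passing recovery study shows the pipeline is correct and calibrated for
this noise model, not that any real campaign's effects are this clean.

`parameter_recovery_report` runs simulate→fit cycles and reports bias, RMSE
and empirical 95% CI coverage per coefficient. The reference value of each
term is the summed truth coefficient over its whole alias class (aliases
enter with sign +1 on the principal fraction), which reduces to the plain
coefficient wherever the resolution leaves the term unconfounded — this is
what makes the resolution IV property ("MEs unbiased even with interactions
in the truth") a testable statement. `familywise_error_rate` estimates the
probability, under a chosen truth, that any Bonferroni-adjusted p-value
falls below α; with a zero-effect truth this is the family-wise type-I
error of the screen.

## Numerical and design choices

- Coded levels are exactly −1/+1; label mapping lives in the factor config.
- Run order is standard (Yates) by default; a seeded shuffle is available
  and recorded. All randomness flows through explicit integer seeds;
  derived seeds come from `numpy.random.SeedSequence` and stay below 2³¹.
- The resolution of a full factorial is reported as the distinguished
  unbounded value `math.inf` (comparisons like `res >= 4` keep working),
  never as a number of its own.
- The infeasible genotypes are expressed as a predicate on three genetic
  factors (PAL-C4H low, ARO7 high, ARO4 high — the two unconstructable gene
  clusters differ only in AROL), not as hard-coded row indices, so they
  survive any column assignment or run reordering.
- Candidate-ranking ties, generator-search ties and column-assignment ties
  all break lexicographically, for bit-reproducibility.
- CSV writers emit `#`-prefixed provenance headers (tool version, generator
  words, content hash) that readers skip; write→read round-trips are
  bit-exact, including factor order and run ids.
- Problem sizes in the test suite: alias oracles are exhaustive for k ≤ 6;
  calibration uses 2000 simulate-fit cycles on the 64-run design (Monte-
  Carlo error ~0.5 points on coverage); the end-to-end campaign study uses
  200 replicates, enough to bound the recovery rate to a few points.

## Known limitations

- Only regular two-level fractions: no mixed-level designs, Plackett-Burman
  or other non-regular orthogonal arrays, D-optimal augmentation, blocking,
  or response-surface (quadratic) follow-up.
- OLS with homoscedastic t-tests: under the multiplicative noise model the
  coefficient estimates stay unbiased and (on orthogonal designs) their
  variance is the run-averaged noise variance over n, so CI coverage stays
  near nominal, but strongly heteroscedastic data would call for WLS or
  robust errors, which are out of scope.
- The generator-search budget makes k much beyond 16 impractical; that is
  far above the intended screening sizes.
- Which factor pair an alias-class label refers to is a convention (the
  lexicographically smallest member); different software choosing different
  generators will label confounded groups differently even when the designs
  are isomorphic.
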