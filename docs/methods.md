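# Methods

## Model and procedure

The package treats a taxa-by-samples count table as phylogenetically
structured compositional data: after zero replacement and closure, only
ratios of abundances carry information, and the phylogeny supplies the
candidate contrasts.  Every quantity is built from isometric log-ratio
(ILR) balances.  For disjoint taxon groups R (r taxa) and S (s taxa),

    x*_{R,S} = sqrt(rs/(r+s)) · ln( g(y_R)/g(y_S) ),   g = geometric mean,

equivalently the inner product of ln y with a unit-norm, zero-sum contrast
vector (+sqrt(s/(r(r+s))) on R, −sqrt(r/(s(r+s))) on S).  Balances are
invariant to per-sample rescaling, and any set of balances built from a
sequential binary partition is orthonormal, so the total compositional
(CLR) variance is conserved: it equals the sum of the balance variances of
any full basis.  Natural logarithms are used throughout so that fitted
balances convert back to geometric-mean fold ratios as
exp(x̂ / sqrt(rs/(r+s))).

Factorization is greedy.  At each iteration, every unused edge of the
unrooted tree defines one candidate: the balance of the two sides of its
bipartition *restricted to the bin of taxa the edge lies in*.  Each
candidate balance is regressed on the sample covariates (ordinary least
squares for the default gaussian/identity family) and scored by the
deviance difference — null deviance minus model deviance, which for the
gaussian family is the explained sum of squares of the balance and hence
the share of the dataset's fixed variance budget captured by the
regression.  The maximizing edge becomes the next factor; its bin splits
in two; contrasts in later iterations stay inside bins, which enforces
orthogonality of the emitted basis.  Polytomies are unproblematic because
candidates are edges, not nodes; the rooted-ILR baseline (one balance per
internal node of the rooted binary tree) is provided for comparison and
does require a fully resolved tree.

Candidate p-values come from the overall-model F-test of each regression
(a likelihood-ratio test against the null model for non-gaussian
families).  A candidate whose balance is constant is degenerate: objective
0, p-value 1, and it stays in the stopping pool so that constants cannot
masquerade as signal.

## Stopping rule

Besides a fixed factor count, the package offers a Kolmogorov–Smirnov
stopping rule: before accepting the factor at each iteration, the current
candidate p-values are tested against Uniform(0, 1); when the KS p-value
P_KS exceeds the threshold (default 0.05) there is no evidence of
remaining signal and iteration stops.  The exact small-sample null
distribution is used for pools of up to 100 p-values, the asymptotic one
beyond.

The KS test is one-sided (D+ statistic: empirical CDF above the uniform,
an excess of small p-values).  This is a deliberate design choice: the
greedy loop removes the smallest p-value from the pool at every iteration,
so after the signal is exhausted the surviving pool is *deficient* in
small p-values; a two-sided test rejects for that direction as well and
can keep a pure-noise factorization alive to D − 1 factors.  Only the
excess-small direction constitutes evidence of remaining signal, and with
the one-sided statistic an all-degenerate pool (every p-value equal to 1)
stops immediately, as it should.

Candidate p-values are dependent — balances of nested edges share taxa —
and the KS calibration inherits that dependence: on pure-noise communities
(D = 50, two balanced environments of 20 samples) the rule continues past
a signal-free iteration in roughly one sixth of datasets rather than the
nominal 5%.  In the stopping simulations this false continuation roughly
offsets the mass of undetectably weak lognormal folds, making the
estimated factor count approximately unbiased for the true clade count
rather than strictly conservative (the acceptance suite computes these
calibration curves; see `tests/test_acceptance.py`).

## Preprocessing defaults

* Prevalence filter (keep taxa present in ≥ m samples) and mean-count
  filter (keep taxa with mean count ≥ c) — thresholds are data-set
  choices, both inclusive.
* Zero replacement: pseudo-count 0.65 added to **zero cells only**, never
  a global shift; nonzero counts pass through bitwise unchanged.
* Closure per sample to unit sum; samples with missing required covariates
  are dropped with a warning before fitting.

## Numerical and algorithmic choices

* Per-iteration candidate fits are vectorized: one contrast matrix times
  the log-composition gives all candidate balances, whose explained SS and
  F-tests are computed against a single QR factorization of the design.
  A unit test pins this path to the per-candidate scalar route.
* Tie-break: equal objectives resolve to the smallest preorder edge id, so
  runs are reproducible and independent of candidate evaluation order.
* Distinct tree edges that induce the same bipartition (the two edges at a
  bifurcating root; chains collapsed after earlier splits) are merged into
  one candidate that records every contributing edge id, rather than
  silently attributing the factor to one of them.
* Sign convention: within a bin, group R (positive side of the contrast)
  is the side *not* containing the bin's lexicographically smallest taxon.
* Monophyly of a bin is judged against the clades of the tree as rooted
  when parsed; the complement ("remainder") side of a factored clade is
  paraphyletic even though it is a bipartition side of the unrooted tree.
* Geometric means are computed as exp(mean(ln ·)) for stability at small
  relative abundances.
* `explained_variance_fraction(result, k)` is the summed objective of the
  first k factors over the total CLR sum of squares.  It reaches 1.0 at
  D − 1 factors only when the covariates explain every balance exactly
  (noiseless model-generated data); on noisy data the full-basis value is
  the dataset-level R² of the regression model.
* BPU amalgamation sums member relative abundances (the observed scale);
  a geometric variant (closure of per-bin geometric means, the scale the
  ILR machinery lives on) is available via `method="geometric"`.
* Predicted BPU abundances invert the fitted balances through the factor
  basis: the k factors form a sequential binary partition of the k + 1
  bins, each bin receives its geometric-mean part, parts are implicitly
  weighted by bin size and re-closed.  This reproduces observed BPUs
  exactly on data that are flat within bins (all the k-factor model
  constrains); within-bin heterogeneity makes summed observed abundances
  differ from the geometric reconstruction.
* lmg dominance enumerates all m! regressor orderings (m ≤ 8), averaging
  each covariate's gain in explained SS; a categorical covariate enters
  with all of its indicator columns at once.  Shares sum to the full
  model's explained SS.

## Simulation generator

`simulate` emulates a two-environment marker-gene survey: ln N_ij i.i.d.
Normal(μ = 8, σ = 0.5) for D = 50 taxa on one fixed random binary tree,
20 samples per environment, with effects applied as clade-level fold
changes in one environment.  Affected clades are drawn uniformly among
clades of size 2 to D/2 — single tips and effects spanning more than half
the community (indistinguishable from a complementary effect on the rest)
are excluded by default, both bounds configurable.  Multiple clades are
disjoint by default.  A master seed spawns independent per-replicate
streams, so any replicate can be re-run in isolation.

The generator produces strictly positive abundances: it exercises the
compositional and phylogenetic structure of the method but not sequencing
sparsity (zeros), overdispersed count noise, or uneven sampling depth.
Passing simulation tests therefore demonstrates correct inference under
lognormal noise with exact clade-level effects; robustness of the
zero-replacement step on sparse real tables is not probed by them.

Experiment sizes used by the test and acceptance suites — 100 replicates
per effect size for the power comparisons, 50 replicates per clade count
for stopping calibration, and exhaustive topology enumeration up to 6 tips
with seeded 80-topology samples of the 7- and 8-tip shape spaces for the
brute-force equivalence check — were chosen to give stable means and full
coverage of small shape space at interactive runtimes.

## Known limitations

* The greedy sequence maximizes each step, not the joint k-factor
  explained variance; no stochastic-restart search is implemented.
* The objective ignores branch lengths; edge-length-weighted objectives
  are a natural extension hook.
* KS stopping is supported only for families with a defined overall-model
  test p-value, and its calibration is approximate under candidate
  dependence (see above).
* Zero handling is the fixed-pseudo-count convention; model-based zero
  replacement is out of scope.
* The tree is taken as known; uncertainty in the phylogeny is not
  propagated into factor confidence.
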