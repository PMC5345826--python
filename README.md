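# phylofactor

Phylogenetic factorization of compositional sequence-count data: a greedy
algorithm that finds the edges of a phylogeny along which microbial
relative abundances change most predictably with sample covariates.

## The problem

Marker-gene surveys (16S/18S) produce tables of counts for thousands of
OTUs across samples, together with a phylogeny relating the OTUs.  Two
structural facts complicate analysis: the data are *compositional* (only
relative abundances are meaningful), and functional traits that drive
responses to environmental gradients arise along *edges* of the phylogeny,
not at Linnaean rank boundaries.  Taxon-by-taxon tests ignore both.

This package analyzes the data on the scale of isometric log-ratio (ILR)
balances.  For disjoint taxon groups R (r taxa) and S (s taxa) of a
composition y, the balance is

    x*_{R,S} = sqrt(rs / (r + s)) * ln( g(y_R) / g(y_S) )

with g the geometric mean.  Each edge e of the (unrooted) tree splits the
taxa into two groups and so defines a candidate balance x*_e.  The greedy
factorization regresses every candidate balance on the covariates,
x*_e ~ f(X), and selects the edge maximizing the explained deviance (for
the default gaussian family: the explained sum of squares, i.e. the share
of the dataset's fixed total compositional variance captured by the
regression).  The winning edge is cut; subsequent iterations restrict
contrasts to taxa within each resulting "bin", which makes successive
balancing elements orthogonal.  After k factors one has an orthonormal
rank-k ILR basis, k + 1 bins ("binned phylogenetic units", BPUs), and
edge-level regression inferences.  Iteration stops at a requested factor
count or when a Kolmogorov–Smirnov test finds no excess of small p-values
among the candidate regressions.

The rooted-ILR transform (balances at each node of the rooted binary tree)
is included as the baseline comparator, along with per-taxon CLR
regression with Benjamini–Hochberg/Bonferroni correction, lmg dominance
analysis for multiple regression, fold-ratio interpretation of fitted
balances, bin taxonomy labels, and a simulation suite for power and
stopping-rule calibration.

## Worked example

```python
import numpy as np, pandas as pd
from phylofactor import (Phylogeny, RegressionSpec, close_to_composition,
                         phylofactorize, balance_to_fold_ratio,
                         explained_variance_fraction)

# five taxa on an unrooted tree; taxa A,B are enriched in tongue samples
tree = Phylogeny.from_newick("((A,B),(C,D),E);")
rng = np.random.default_rng(0)
counts = pd.DataFrame(np.exp(rng.normal(8, 0.5, (5, 12))),
                      index=list("ABCDE"),
                      columns=[f"s{j}" for j in range(12)])
meta = pd.DataFrame({"site": ["gut"]*6 + ["tongue"]*6}, index=counts.columns)
counts.loc[["A", "B"], meta["site"] == "tongue"] *= 4.0

comp = close_to_composition(counts)
result = phylofactorize(comp, tree, RegressionSpec(("site",)), meta, stop="ks")

print(f"factors: {result.n_factors}, bins: {len(result.bins)}")
f1 = result.factors[0]
print(f"factor 1 splits {sorted(f1.side_S)} from {sorted(f1.side_R)}")
print(f"  objective (explained SS) = {f1.candidate.objective:.3f}, "
      f"p = {f1.candidate.p_value:.2e}")
beta = f1.candidate.coefficients
r, s = len(f1.side_R), len(f1.side_S)
gut = balance_to_fold_ratio(beta["Intercept"], r, s)
tongue = balance_to_fold_ratio(beta["Intercept"] + beta["site[tongue]"], r, s)
print(f"  g(R)/g(S) fold ratio: {gut:.2f} in gut, {tongue:.2f} in tongue")
print(f"variance explained by factor 1: "
      f"{100 * explained_variance_fraction(result, 1):.1f}%")
```

prints:

```
factors: 1, bins: 2
factor 1 splits ['A', 'B'] from ['C', 'D', 'E']
  objective (explained SS) = 10.133, p = 1.04e-05
  g(R)/g(S) fold ratio: 1.36 in gut, 0.25 in tongue
variance explained by factor 1: 52.9%
```

The KS rule stopped after one factor: the edge separating {A, B} — whose
geometric mean is 1/0.25 = 4 times higher relative to the rest in the
tongue than expected, matching the simulated 4-fold enrichment — and no
evidence of further signal.  That single balance carries 52.9% of the
total compositional variance.

The same pipeline is available from the shell:

```sh
phylofactor run --table counts.tsv --tree tree.nwk --metadata meta.tsv \
    --covariates site --outdir out/
phylofactor summarize out/ -k 3
phylofactor simulate power1 --effect 6 --replicates 100 --seed 1 --outdir sim/
```

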