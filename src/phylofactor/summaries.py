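"""Post-hoc analysis of a factorization.

After k factors the taxa fall into k + 1 disjoint bins; summing the relative
abundances of each bin's members gives a low-dimensional composition of
"binned phylogenetic units" (BPUs).  This module provides the bin/BPU views,
fold-ratio interpretation of fitted balances, explained-variance accounting,
taxonomy labels for bins, the per-taxon CLR + FDR comparison analysis, and
lmg dominance analysis for multiple regression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import ilr
from .core import PhylofactorResult, RegressionSpec, _gaussian_fit_stats
from .io_prep import CompositionTable, clr_transform
from .phylo_tree import TaxonBin, split_bin

__all__ = [
    "BpuTable",
    "DominanceResult",
    "bins_after",
    "amalgamate_bpu",
    "balance_to_fold_ratio",
    "explained_variance_fraction",
    "predicted_bpu",
    "shortest_unique_prefix",
    "clr_significance",
    "lmg_dominance",
    "ordination_coordinates",
]


@dataclass
class BpuTable:
    """Amalgamated bin-level composition: bins x samples, columns sum to 1."""

    membership: dict[str, int]  # taxon id -> bin index
    composition: pd.DataFrame
    monophyletic: list[bool]


@dataclass
class DominanceResult:
    """lmg relative importance of each regressor in one balance regression."""

    shares: pd.Series  # explained SS attributable to each covariate
    explained_ss: float
    r_squared: float

    @property
    def pct_of_explained(self) -> pd.Series:
        if self.explained_ss <= 0:
            return self.shares * np.nan
        return 100.0 * self.shares / self.explained_ss


def bins_after(result: PhylofactorResult, k: int) -> list[TaxonBin]:
    """The k + 1 bins produced by the first k factors (replayed splits)."""
    if not 0 <= k <= result.n_factors:
        raise ValueError(f"k must be in [0, {result.n_factors}], got {k}")
    bins = [TaxonBin(frozenset(result.taxon_order), monophyletic=True, origin=())]
    for f in result.factors[:k]:
        idx = next(i for i, b in enumerate(bins) if b.members == f.parent_members)
        bin_R, bin_S = split_bin(bins[idx], f.side_R, f.side_S, result.tree, f.index)
        bins[idx : idx + 1] = [bin_R, bin_S]
    return bins


def amalgamate_bpu(
    comp: CompositionTable, bins: list[TaxonBin], method: str = "sum"
) -> BpuTable:
    """Collapse taxa to bins.

    ``method="sum"`` (default) adds member relative abundances, keeping the
    observed mass of each bin; ``method="geometric"`` takes the closure of
    per-bin geometric means, the scale the ILR machinery itself lives on.
    """
    members_all = frozenset().union(*(b.members for b in bins)) if bins else frozenset()
    if members_all != frozenset(comp.taxa) or sum(len(b.members) for b in bins) != len(comp.taxa):
        raise ValueError("bins must partition the taxa of the composition")
    values = comp.values
    taxon_idx = {t: i for i, t in enumerate(comp.taxa)}
    rows = []
    for b in bins:
        idx = [taxon_idx[t] for t in sorted(b.members)]
        if method == "sum":
            rows.append(values[idx].sum(axis=0))
        elif method == "geometric":
            rows.append(np.exp(np.log(values[idx]).mean(axis=0)))
        else:
            raise ValueError(f"unknown method {method!r}")
    mat = np.array(rows)
    mat = mat / mat.sum(axis=0, keepdims=True)
    composition = pd.DataFrame(mat, index=range(len(bins)), columns=comp.samples)
    membership = {t: i for i, b in enumerate(bins) for t in b.members}
    return BpuTable(membership, composition, [b.monophyletic for b in bins])


def balance_to_fold_ratio(fitted_balance: float, r: int, s: int) -> float:
    """Geometric-mean abundance ratio g(y_R)/g(y_S) implied by a balance."""
    if r < 1 or s < 1:
        raise ValueError("group sizes must be >= 1")
    return float(np.exp(fitted_balance / np.sqrt(r * s / (r + s))))


def explained_variance_fraction(result: PhylofactorResult, k: int) -> float:
    """Fraction of total compositional variance captured by the first k
    factors' regressions: (sum of their objectives) / total SS."""
    if not 0 <= k <= result.n_factors:
        raise ValueError(f"k must be in [0, {result.n_factors}], got {k}")
    if k == 0:
        return 0.0
    return float(sum(f.candidate.objective for f in result.factors[:k]) / result.total_ss)


def predicted_bpu(result: PhylofactorResult, k: int, newX: pd.DataFrame) -> BpuTable:
    """BPU relative abundances predicted by the first k fitted factors.

    The k factors form a sequential binary partition of the k + 1 bins, so
    the fitted balances at ``newX`` define bin-level geometric-mean parts by
    ILR inversion; each part is implicitly weighted by its bin size (every
    member taxon carries the part) and re-closed, putting predictions on the
    same summed scale as observed BPUs.
    """
    if not 0 <= k <= result.n_factors:
        raise ValueError(f"k must be in [0, {result.n_factors}], got {k}")
    bins = bins_after(result, k)
    if k == 0:
        ones = pd.DataFrame(
            np.ones((1, len(newX))), index=[0], columns=list(newX.index)
        )
        return BpuTable({t: 0 for t in result.taxon_order}, ones, [bins[0].monophyletic])
    fitted = result.predict_balances(newX).iloc[:k]
    basis = ilr.IlrBasis(
        [f.element for f in result.factors[:k]],
        provenance=[f.index for f in result.factors[:k]],
    )
    taxon_comp = ilr.inverse_ilr(fitted, basis, sample_ids=list(newX.index))
    return amalgamate_bpu(taxon_comp, bins, method="sum")


def shortest_unique_prefix(
    taxonomy: dict[str, str], bins: list[TaxonBin]
) -> list[list[str]]:
    """Label each bin by the shortest lineage prefixes unique to it.

    For every member taxon the shortest semicolon-delimited lineage prefix
    matching no taxon outside the bin is found; the deduplicated set of
    these prefixes covers the bin and matches nothing outside it.  Taxa
    whose full lineage also occurs outside the bin fall back to their id.
    """
    def prefixes(lineage: str) -> list[str]:
        ranks = [p.strip() for p in lineage.split(";")]
        return [";".join(ranks[: i + 1]) for i in range(len(ranks))]

    labels: list[list[str]] = []
    for b in bins:
        outside = [taxonomy[t] for t in taxonomy if t not in b.members]
        chosen: list[str] = []
        for t in sorted(b.members):
            lineage = taxonomy.get(t)
            label = None
            if lineage is not None:
                for pre in prefixes(lineage):
                    if not any(o == pre or o.startswith(pre + ";") for o in outside):
                        label = pre
                        break
            if label is None:
                label = t  # id fallback: lineage absent or shared outside the bin
            if label not in chosen:
                chosen.append(label)
        labels.append(sorted(chosen))
    return labels


def clr_significance(
    comp: CompositionTable, spec: RegressionSpec, X: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-taxon regression of CLR values on the covariates.

    Returns a DataFrame indexed by taxon with the overall-model F-test
    p-value, the Benjamini–Hochberg q-value with its discovery flag at
    level ``fdr``, and a Bonferroni flag at the same nominal level.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    X = X.loc[list(comp.samples)]
    A, _ = spec.build_design(X)
    Q, _ = np.linalg.qr(A)
    clr = clr_transform(comp).to_numpy()
    ess, pvals = _gaussian_fit_stats(clr, Q, A.shape[1])
    reject, qvals, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    bonf = pvals < fdr / len(pvals)
    return pd.DataFrame(
        {
            "p": pvals,
            "q": qvals,
            "significant": reject,
            "bonferroni": bonf,
            "explained_ss": ess,
        },
        index=list(comp.taxa),
    )


def lmg_dominance(
    balance: np.ndarray, spec: RegressionSpec, X: pd.DataFrame
) -> DominanceResult:
    """lmg relative importance: average over all orderings of regressors of
    the increase in explained SS when each regressor enters the model.

    Regressors are the named covariates (a categorical covariate enters with
    all its indicator columns at once).  Shares sum to the full model's
    explained SS.
    """
    covs = list(spec.covariates)
    m = len(covs)
    if m < 1:
        raise ValueError("need at least one regressor")
    if m > 8:
        raise ValueError("lmg enumerates m! orderings; m must be <= 8")
    y = np.asarray(balance, dtype=float)

    # columns of the design belonging to each covariate
    A, names = spec.build_design(X)
    col_groups = {
        cov: [j for j, nm in enumerate(names) if nm == cov or nm.startswith(cov + "[")]
        for cov in covs
    }
    for cov, cols in col_groups.items():
        if not cols:
            raise ValueError(f"covariate {cov!r} contributes no design columns")

    tss = float(((y - y.mean()) ** 2).sum())
    cache: dict[frozenset, float] = {}

    def ess_of(subset: frozenset) -> float:
        if subset not in cache:
            cols = [0] + sorted(j for cov in subset for j in col_groups[cov])
            sub = A[:, cols]
            Q, _ = np.linalg.qr(sub)
            proj = Q.T @ y
            cache[subset] = float(proj @ proj - len(y) * y.mean() ** 2)
        return cache[subset]

    shares = {cov: 0.0 for cov in covs}
    orderings = list(itertools.permutations(covs))
    for order in orderings:
        have: frozenset = frozenset()
        for cov in order:
            gain = ess_of(have | {cov}) - ess_of(have)
            shares[cov] += gain
            have = have | {cov}
    shares = pd.Series({cov: v / len(orderings) for cov, v in shares.items()})
    full = ess_of(frozenset(covs))
    return DominanceResult(shares, full, full / tss if tss > 0 else np.nan)


def ordination_coordinates(result: PhylofactorResult, k: int) -> pd.DataFrame:
    """Samples x first-k projected balances, ready for scatter plots."""
    if not 1 <= k <= result.n_factors:
        raise ValueError(f"k must be in [1, {result.n_factors}], got {k}")
    return result.balances.iloc[:k].T
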