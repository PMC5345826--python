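"""Greedy phylogenetic factorization of compositional data.

Each iteration considers every unused edge of the tree, restricted to the
bin of taxa the edge lives in, builds the corresponding ILR balance, and
regresses it on the sample covariates.  The objective for an edge is the
difference between the null deviance and the model deviance of that
regression — for the default gaussian family this is the explained sum of
squares of the balance, so the greedy choice is the edge capturing the most
of the dataset's (fixed) total compositional variance.  The winning edge is
cut, its bin splits in two, and the process repeats.

Restricting every contrast to the taxa of a single bin makes successive
balancing elements mutually orthogonal, so after k factors the result is an
orthonormal rank-k ILR basis plus k + 1 bins of taxa.

Stopping: either a fixed factor count, or a Kolmogorov–Smirnov test of the
current iteration's candidate regression p-values against Uniform(0, 1) —
when the p-values look uniform (P_KS above the threshold) there is no
evidence of remaining phylogenetic signal and iteration stops *before*
accepting that iteration's factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ilr
from .io_prep import CompositionTable, clr_transform
from .phylo_tree import (
    CandidatePartition,
    Phylogeny,
    TaxonBin,
    candidate_partitions,
    prune_to_taxa,
    split_bin,
)

__all__ = [
    "RegressionSpec",
    "CandidateFit",
    "FactorFit",
    "PhylofactorResult",
    "total_variance",
    "fit_candidate",
    "choose_factor",
    "ks_stop_check",
    "phylofactorize",
]

_TOL = 1e-12


@dataclass(frozen=True)
class RegressionSpec:
    """Model for the per-edge regressions x* ~ f(X).

    ``covariates`` name columns of the sample metadata; categorical columns
    are expanded to treatment-coded indicators (sorted levels, first level as
    reference) and an intercept is always included.  The default gaussian
    family with identity link makes the deviance difference an explained sum
    of squares; other one-parameter GLM families (``"poisson"``,
    ``"binomial"``) are fit via statsmodels with a likelihood-ratio p-value.
    """

    covariates: tuple[str, ...]
    family: str = "gaussian"

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.family not in ("gaussian", "poisson", "binomial"):
            raise ValueError(f"unsupported family: {self.family!r}")

    def design_info(self, meta: pd.DataFrame) -> list[tuple[str, tuple[str, ...] | None]]:
        """Per-covariate coding: (name, None) for numeric, (name, levels)
        for categorical (sorted levels, first as reference)."""
        missing = [c for c in self.covariates if c not in meta.columns]
        if missing:
            raise ValueError(f"covariates not in metadata: {missing}")
        info = []
        for cov in self.covariates:
            series = meta[cov]
            if pd.api.types.is_numeric_dtype(series) and series.dtype != bool:
                info.append((cov, None))
            else:
                info.append((cov, tuple(sorted(map(str, series.unique())))))
        return info

    def build_design(
        self, meta: pd.DataFrame, info=None, validate: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Design matrix (n x p, intercept first) and its column names.

        Passing the ``info`` of a previous build reproduces the fitted
        columns for new samples (e.g., for prediction), where rank and
        sample-count validation do not apply.
        """
        if info is None:
            info = self.design_info(meta)
        n = len(meta)
        cols: list[np.ndarray] = [np.ones(n)]
        names = ["Intercept"]
        for cov, levels in info:
            if cov not in meta.columns:
                raise ValueError(f"covariate {cov!r} not in metadata")
            series = meta[cov]
            if series.isna().any():
                raise ValueError(f"covariate {cov!r} has missing values")
            if levels is None:
                cols.append(series.to_numpy(dtype=float))
                names.append(cov)
            else:
                unknown = set(map(str, series.unique())) - set(levels)
                if unknown:
                    raise ValueError(f"unseen level(s) of {cov!r}: {sorted(unknown)}")
                for level in levels[1:]:
                    cols.append((series.astype(str) == level).to_numpy(dtype=float))
                    names.append(f"{cov}[{level}]")
        A = np.column_stack(cols)
        if validate:
            if np.linalg.matrix_rank(A) < A.shape[1]:
                raise ValueError("design matrix is rank-deficient")
            if n < A.shape[1] + 2:
                raise ValueError(
                    f"need at least {A.shape[1] + 2} samples for {A.shape[1]} coefficients"
                )
        return A, names


@dataclass(frozen=True)
class CandidateFit:
    """One edge's regression: objective (deviance drop) and its p-value."""

    edge_ids: tuple[int, ...]
    side_R: frozenset[str]
    side_S: frozenset[str]
    bin_index: int
    objective: float
    p_value: float
    coefficients: pd.Series | None = None

    @property
    def edge_id(self) -> int:
        return self.edge_ids[0]


@dataclass(frozen=True)
class FactorFit:
    """One accepted greedy step."""

    index: int  # 1-based factor number
    candidate: CandidateFit
    element: ilr.BalancingElement
    fitted: np.ndarray  # fitted balances at the observed covariates
    parent_members: frozenset[str]

    @property
    def side_R(self) -> frozenset[str]:
        return self.candidate.side_R

    @property
    def side_S(self) -> frozenset[str]:
        return self.candidate.side_S


@dataclass
class PhylofactorResult:
    factors: list[FactorFit]
    bins: list[TaxonBin]
    basis: ilr.IlrBasis
    balances: pd.DataFrame  # factors x samples, observed projections
    stopping: list[dict]  # per-iteration: n_candidates, P_KS (if KS rule)
    total_variance: float
    total_ss: float
    taxon_order: tuple[str, ...]
    sample_ids: tuple[str, ...]
    spec: RegressionSpec
    design_columns: list[str]
    design_info: list
    tree: Phylogeny
    stop_rule: str

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def predict_balances(self, newX: pd.DataFrame) -> pd.DataFrame:
        """Fitted balances of every factor at new covariate values."""
        A, names = self.spec.build_design(newX, info=self.design_info, validate=False)
        if names != self.design_columns:
            raise ValueError("new covariates produce a different design than the fit")
        rows = [A @ f.candidate.coefficients.to_numpy() for f in self.factors]
        return pd.DataFrame(
            np.array(rows).reshape(len(self.factors), len(newX)),
            index=[f.index for f in self.factors],
            columns=list(newX.index),
        )

    def factor_table(self) -> pd.DataFrame:
        """Per-factor summary: edge ids, group sizes, objective, p-value."""
        rows = []
        for f in self.factors:
            rows.append(
                {
                    "factor": f.index,
                    "edge_ids": ",".join(map(str, f.candidate.edge_ids)),
                    "r": len(f.side_R),
                    "s": len(f.side_S),
                    "objective": f.candidate.objective,
                    "pct_total_variance": 100.0 * f.candidate.objective / self.total_ss,
                    "p_value": f.candidate.p_value,
                    "taxa_R": ";".join(sorted(f.side_R)),
                    "taxa_S": ";".join(sorted(f.side_S)),
                }
            )
        return pd.DataFrame(rows)


def total_variance(comp: CompositionTable) -> float:
    """Total compositional variance: sum of CLR row variances (ddof 1)."""
    if len(comp.samples) < 2:
        raise ValueError("total variance needs at least 2 samples")
    clr = clr_transform(comp).to_numpy()
    return float(clr.var(axis=1, ddof=1).sum())


def _gaussian_fit_stats(B: np.ndarray, Q: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Explained SS and F-test p-values for each row of B regressed on the
    design whose orthonormal column basis is Q (intercept in its span)."""
    n = B.shape[1]
    proj = B @ Q
    model_ss = np.einsum("ij,ij->i", proj, proj)
    means = B.mean(axis=1)
    tss = np.einsum("ij,ij->i", B, B) - n * means**2
    ess = np.clip(model_ss - n * means**2, 0.0, None)
    rss = np.clip(tss - ess, 0.0, None)
    df_model = rank - 1
    df_resid = n - rank
    pvals = np.ones(len(B))
    ok = tss > _TOL * np.maximum(1.0, n * means**2 + 1.0)
    ess = np.where(ok, ess, 0.0)
    if df_model <= 0 or df_resid <= 0:
        raise ValueError("no residual or model degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ess / df_model) / (rss / df_resid)
    F = np.where(ok, F, np.nan)
    finite = ok & np.isfinite(F)
    pvals[finite] = stats.f.sf(F[finite], df_model, df_resid)
    pvals[ok & ~np.isfinite(F)] = 0.0  # perfect fit: RSS == 0
    return ess, pvals


def fit_candidate(
    balance: np.ndarray, spec: RegressionSpec, X: pd.DataFrame, candidate: CandidatePartition | None = None
) -> CandidateFit:
    """Regress one balance on the covariates.

    Returns the deviance-difference objective, the overall-model test
    p-value (F for gaussian, LRT otherwise), and the fitted coefficients.
    A constant balance is a degenerate fit: objective 0, p-value 1.
    """
    y = np.asarray(balance, dtype=float)
    A, names = spec.build_design(X)
    if len(y) != A.shape[0]:
        raise ValueError("balance and covariates have different sample counts")
    if spec.family == "gaussian":
        Q, _ = np.linalg.qr(A)
        ess, pvals = _gaussian_fit_stats(y[None, :], Q, A.shape[1])
        objective, p_value = float(ess[0]), float(pvals[0])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    else:
        import statsmodels.api as sm

        family = {"poisson": sm.families.Poisson, "binomial": sm.families.Binomial}[spec.family]()
        model = sm.GLM(y, A, family=family).fit()
        objective = float(model.null_deviance - model.deviance)
        df_model = A.shape[1] - 1
        p_value = float(stats.chi2.sf(max(objective, 0.0), df_model)) if df_model else 1.0
        beta = model.params
    edge_ids = candidate.edge_ids if candidate is not None else ()
    side_R = candidate.side_R if candidate is not None else frozenset()
    side_S = candidate.side_S if candidate is not None else frozenset()
    bin_index = candidate.bin_index if candidate is not None else 0
    return CandidateFit(
        edge_ids, side_R, side_S, bin_index, objective, p_value, pd.Series(beta, index=names)
    )


def choose_factor(candidates: list[CandidateFit]) -> CandidateFit:
    """Candidate with the maximal objective; ties go to the smallest edge id."""
    if not candidates:
        raise ValueError("no candidates to choose from")
    return min(candidates, key=lambda c: (-c.objective, c.edge_id))


def ks_stop_check(p_values) -> float:
    """P_KS of a one-sample KS test of p-values against Uniform(0, 1).

    The test is one-sided in the direction that constitutes evidence of
    remaining signal — an excess of small p-values (empirical CDF above the
    uniform, the D+ statistic).  A deficit of small p-values, which the
    greedy loop itself produces by repeatedly removing the strongest
    candidate, is not signal and must not keep the iteration alive; it also
    makes an all-degenerate pool (every p-value 1) stop immediately.  The
    exact small-sample null distribution is used for up to 100 values, the
    asymptotic one beyond.  The caller stops factoring when the returned
    P_KS exceeds its threshold.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    method = "exact" if p.size <= 100 else "asymp"
    return float(
        stats.kstest(p, stats.uniform.cdf, alternative="greater", method=method).pvalue
    )


def _contrast_row(cand: CandidatePartition, index: dict[str, int], D: int) -> np.ndarray:
    r, s = len(cand.side_R), len(cand.side_S)
    row = np.zeros(D)
    pos = np.sqrt(s / (r * (r + s)))
    neg = -np.sqrt(r / (s * (r + s)))
    for t in cand.side_R:
        row[index[t]] = pos
    for t in cand.side_S:
        row[index[t]] = neg
    return row


def phylofactorize(
    comp: CompositionTable,
    tree: Phylogeny,
    spec: RegressionSpec,
    X: pd.DataFrame,
    stop="ks",
    ks_threshold: float = 0.05,
) -> PhylofactorResult:
    """Run the greedy factorization.

    Parameters
    ----------
    comp
        Strictly positive composition, taxa x samples.
    tree
        Phylogeny whose tips cover the composition's taxa; extra tips are
        pruned with a warning, missing taxa are a hard error.
    spec, X
        Regression specification and per-sample covariates (indexed by
        sample id; must cover every sample of ``comp``).
    stop
        ``"ks"`` (default) stops when the KS test of the current iteration's
        candidate p-values yields P_KS > ``ks_threshold``, evaluated before
        accepting that iteration's factor; an integer runs exactly that many
        factors (capped at D − 1).
    """
    taxa = frozenset(comp.taxa)
    missing = taxa - tree.tip_set
    if missing:
        raise ValueError(f"taxa absent from the tree: {sorted(missing)}")
    if tree.tip_set - taxa:
        warnings.warn(
            f"pruning {len(tree.tip_set - taxa)} tree tip(s) absent from the table",
            stacklevel=2,
        )
        tree = prune_to_taxa(tree, taxa)

    sample_missing = [s for s in comp.samples if s not in X.index]
    if sample_missing:
        raise ValueError(f"samples absent from metadata: {sample_missing}")
    X = X.loc[list(comp.samples)]

    if isinstance(stop, int) and not isinstance(stop, bool):
        max_factors = min(stop, len(comp.taxa) - 1)
        use_ks = False
        if stop < 0:
            raise ValueError("factor count must be >= 0")
    elif stop == "ks":
        max_factors = len(comp.taxa) - 1
        use_ks = True
    else:
        raise ValueError(f"stop must be an integer or 'ks', got {stop!r}")

    taxon_order = tuple(comp.taxa)
    index = {t: i for i, t in enumerate(taxon_order)}
    L = np.log(comp.values)
    design_info = spec.design_info(X)
    A, design_names = spec.build_design(X, info=design_info)
    Q, _ = np.linalg.qr(A)
    rank = A.shape[1]
    gaussian = spec.family == "gaussian"

    bins = [TaxonBin(taxa, monophyletic=True, origin=())]
    used_edges: set[int] = set()
    factors: list[FactorFit] = []
    stopping: list[dict] = []

    while len(factors) < max_factors:
        cands = candidate_partitions(bins, tree, used_edges)
        if not cands:
            break
        C = np.array([_contrast_row(c, index, len(taxon_order)) for c in cands])
        B = C @ L
        if gaussian:
            objectives, pvals = _gaussian_fit_stats(B, Q, rank)
        else:
            fits = [fit_candidate(B[i], spec, X, cands[i]) for i in range(len(cands))]
            objectives = np.array([f.objective for f in fits])
            pvals = np.array([f.p_value for f in fits])

        record = {"iteration": len(factors) + 1, "n_candidates": len(cands)}
        if use_ks:
            record["P_KS"] = ks_stop_check(pvals)
        stopping.append(record)
        if use_ks and record["P_KS"] > ks_threshold:
            break

        order = min(
            range(len(cands)), key=lambda i: (-objectives[i], cands[i].edge_id)
        )
        winner = cands[order]
        beta, *_ = np.linalg.lstsq(A, B[order], rcond=None)
        cand_fit = CandidateFit(
            winner.edge_ids,
            winner.side_R,
            winner.side_S,
            winner.bin_index,
            float(objectives[order]),
            float(pvals[order]),
            pd.Series(beta, index=design_names),
        )
        element = ilr.balancing_element(winner.side_R, winner.side_S, taxon_order)
        fitted = A @ beta
        k = len(factors) + 1
        parent = bins[winner.bin_index]
        bin_R, bin_S = split_bin(parent, winner.side_R, winner.side_S, tree, k)
        bins[winner.bin_index : winner.bin_index + 1] = [bin_R, bin_S]
        used_edges.update(winner.edge_ids)
        factors.append(FactorFit(k, cand_fit, element, fitted, parent.members))

    basis = ilr.IlrBasis([f.element for f in factors], provenance=[f.index for f in factors])
    balances = (
        ilr.project(comp, basis)
        if factors
        else pd.DataFrame(np.zeros((0, len(comp.samples))), columns=comp.samples)
    )
    clr = clr_transform(comp).to_numpy()
    tv = float(clr.var(axis=1, ddof=1).sum())
    tss = float(((clr - clr.mean(axis=1, keepdims=True)) ** 2).sum())
    return PhylofactorResult(
        factors=factors,
        bins=bins,
        basis=basis,
        balances=balances,
        stopping=stopping,
        total_variance=tv,
        total_ss=tss,
        taxon_order=taxon_order,
        sample_ids=tuple(comp.samples),
        spec=spec,
        design_columns=design_names,
        design_info=design_info,
        tree=tree,
        stop_rule="ks" if use_ks else f"n_factors={max_factors}",
    )
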