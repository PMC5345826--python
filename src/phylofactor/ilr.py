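"""Isometric log-ratio balances and bases.

A balance contrasts two disjoint taxon groups R (r taxa) and S (s taxa) of a
composition y:

    x*_{R,S} = sqrt(rs / (r + s)) * ln( g(y_R) / g(y_S) )

where g is the geometric mean.  Equivalently, x* is the inner product of
ln y with a unit-norm, zero-sum contrast vector carrying +sqrt(s/(r(r+s)))
on R and -sqrt(r/(s(r+s))) on S.  A set of such vectors built from a
sequential binary partition is orthonormal, so total compositional (CLR)
variance is conserved: it equals the sum of the balance variances of any
full basis.  Balances are invariant to per-sample rescaling of abundances,
which is what makes them valid statistics for sequence-count data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_prep import CompositionTable

__all__ = [
    "BalancingElement",
    "IlrBasis",
    "balancing_element",
    "ilr_coordinate",
    "rooted_ilr_transform",
    "project",
    "inverse_ilr",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class BalancingElement:
    """Unit-norm zero-sum contrast vector over a fixed taxon order."""

    coefficients: np.ndarray
    group_R: frozenset[str]
    group_S: frozenset[str]
    taxon_order: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))


class IlrBasis:
    """An ordered collection of pairwise-orthogonal balancing elements."""

    def __init__(self, elements: list[BalancingElement], provenance=None):
        self.elements = list(elements)
        self.provenance = list(provenance) if provenance is not None else list(range(len(elements)))
        if self.elements:
            orders = {e.taxon_order for e in self.elements}
            if len(orders) != 1:
                raise ValueError("basis elements must share one taxon order")
            self.taxon_order = self.elements[0].taxon_order
            V = self.matrix
            gram = V.T @ V
            if not np.allclose(gram, np.eye(len(self.elements)), atol=_ORTHO_TOL):
                raise ValueError("basis elements are not orthonormal")
        else:
            self.taxon_order = ()

    @property
    def matrix(self) -> np.ndarray:
        """Contrast matrix V, taxa x elements."""
        if not self.elements:
            return np.zeros((len(self.taxon_order), 0))
        return np.column_stack([e.coefficients for e in self.elements])

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)


def balancing_element(R, S, taxon_order) -> BalancingElement:
    """Contrast vector for groups R (positive side) and S (negative side)."""
    R, S = frozenset(R), frozenset(S)
    taxon_order = tuple(taxon_order)
    if not R or not S:
        raise ValueError("R and S must be nonempty")
    if R & S:
        raise ValueError(f"R and S overlap: {sorted(R & S)}")
    known = set(taxon_order)
    if not (R <= known and S <= known):
        raise ValueError("R and S must be subsets of taxon_order")
    r, s = len(R), len(S)
    coeffs = np.zeros(len(taxon_order))
    pos = np.sqrt(s / (r * (r + s)))
    neg = -np.sqrt(r / (s * (r + s)))
    for i, t in enumerate(taxon_order):
        if t in R:
            coeffs[i] = pos
        elif t in S:
            coeffs[i] = neg
    return BalancingElement(coeffs, R, S, taxon_order)


def ilr_coordinate(comp: CompositionTable, R, S) -> np.ndarray:
    """Balance of groups R vs S for every sample of a composition."""
    R, S = frozenset(R), frozenset(S)
    element = balancing_element(R, S, comp.taxa)
    return element.coefficients @ np.log(comp.values)


def rooted_ilr_transform(comp: CompositionTable, sbp) -> pd.DataFrame:
    """ILR balances for every row of a sequential binary partition.

    Returns a (D − 1) x samples DataFrame in SBP row order.
    """
    basis = IlrBasis([balancing_element(R, S, comp.taxa) for R, S in sbp])
    covered = frozenset().union(*(R | S for R, S in sbp)) if sbp else frozenset()
    if covered != frozenset(comp.taxa) or len(sbp) != len(comp.taxa) - 1:
        raise ValueError("SBP must cover all taxa with D - 1 rows")
    return project(comp, basis)


def project(comp: CompositionTable, basis: IlrBasis) -> pd.DataFrame:
    """Project a composition onto a basis: one balance row per element."""
    if len(basis) == 0:
        return pd.DataFrame(np.zeros((0, len(comp.samples))), columns=comp.samples)
    if basis.taxon_order != tuple(comp.taxa):
        raise ValueError("basis taxon order does not match composition")
    balances = basis.matrix.T @ np.log(comp.values)
    return pd.DataFrame(balances, index=list(basis.provenance), columns=comp.samples)


def inverse_ilr(balances, basis: IlrBasis, sample_ids=None) -> CompositionTable:
    """Composition whose projection on ``basis`` equals ``balances``.

    With a full (D − 1)-element basis this inverts :func:`project` exactly;
    with a partial basis it returns the closure of exp(V x*), which carries
    the between-group geometric structure only (within-group ratios are
    flattened to equality).
    """
    if isinstance(balances, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(balances.columns)
        balances = balances.to_numpy(dtype=float)
    balances = np.atleast_2d(np.asarray(balances, dtype=float))
    if balances.shape[0] != len(basis):
        raise ValueError("balance rows must align with basis elements")
    log_parts = basis.matrix @ balances
    parts = np.exp(log_parts - log_parts.max(axis=0, keepdims=True))
    closed = parts / parts.sum(axis=0, keepdims=True)
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(balances.shape[1])]
    return CompositionTable(
        pd.DataFrame(closed, index=list(basis.taxon_order), columns=sample_ids)
    )
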