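"""Independent brute-force reference for the greedy factorization.

Deliberately shares no code path with the package: bipartitions are taken
straight from a dendropy parse, balances are evaluated with scipy's gmean
via the closed-form definition, and regressions are solved per candidate
with numpy lstsq.  Used to verify that every greedy step attains the
exhaustive maximum over all distinct induced bin splits.
"""

import dendropy
import numpy as np
from scipy.stats import gmean


def newick_bipartition_sides(newick: str) -> list[frozenset]:
    """Tip set below each edge of the tree as parsed (one per non-root node)."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    sides = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        sides.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return sides


def balance_value(comp_df, R, S) -> np.ndarray:
    r, s = len(R), len(S)
    gR = gmean(comp_df.loc[sorted(R)].to_numpy(), axis=0)
    gS = gmean(comp_df.loc[sorted(S)].to_numpy(), axis=0)
    return np.sqrt(r * s / (r + s)) * np.log(gR / gS)


def explained_ss(y: np.ndarray, x: np.ndarray) -> float:
    """ESS of OLS of y on [1, x] via lstsq residuals."""
    A = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return tss - float((resid**2).sum())


def brute_force_step(comp_df, sides, bins, x):
    """Exhaustive scoring of one greedy step.

    Enumerates all distinct splits of every current bin induced by any tree
    bipartition, scores each by explained SS, and returns
    (best_objective, argmax split set) where splits are frozenset({A, B}).
    """
    candidates = {}
    for bin_ in bins:
        if len(bin_) < 2:
            continue
        for side in sides:
            A = side & bin_
            B = bin_ - A
            if A and B:
                candidates[frozenset((A, B))] = (A, B)
    if not candidates:
        return None
    scored = {
        key: explained_ss(balance_value(comp_df, A, B), x)
        for key, (A, B) in candidates.items()
    }
    best = max(scored.values())
    argmax = {k for k, v in scored.items() if v >= best - 1e-9 * max(1.0, abs(best))}
    return best, argmax
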