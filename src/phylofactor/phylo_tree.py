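"""Phylogeny handling: edge bipartitions, bins, and candidate partitions.

The factorization algorithm views the phylogeny as an *unrooted* topology:
every edge splits the tips into two disjoint sets (a bipartition), and each
greedy step picks one edge whose bipartition — restricted to the bin of taxa
it lives in — best separates taxa by their response to the covariates.

Edges are numbered by a deterministic preorder traversal of the tree as
parsed, so runs are reproducible.  Two distinct edges of the parsed (rooted)
tree can induce the same unrooted bipartition (the two root-adjacent edges of
a bifurcating root; chains collapsed by pruning): such duplicates are merged
into a single bipartition that records every contributing edge id.

Branch lengths are parsed but play no role in the objective.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Phylogeny",
    "EdgeBipartition",
    "TaxonBin",
    "CandidatePartition",
    "read_newick",
    "prune_to_taxa",
    "edge_bipartitions",
    "rooted_sbp",
    "split_bin",
    "candidate_partitions",
    "enumerate_unrooted_topologies",
]


@dataclass(frozen=True)
class EdgeBipartition:
    """The two disjoint tip sets separated by one edge (or a merged chain).

    ``edge_ids`` lists every preorder edge id inducing this bipartition,
    sorted ascending; the first is the canonical id used for tie-breaking.
    """

    edge_ids: tuple[int, ...]
    side_R: frozenset[str]
    side_S: frozenset[str]

    @property
    def edge_id(self) -> int:
        return self.edge_ids[0]


@dataclass(frozen=True)
class TaxonBin:
    """A group of taxa left unsplit after some number of factors."""

    members: frozenset[str]
    monophyletic: bool
    origin: tuple[int, ...] = ()  # factor indices that carved this bin out


@dataclass(frozen=True)
class CandidatePartition:
    """One admissible split of one bin, induced by unused tree edge(s)."""

    edge_ids: tuple[int, ...]
    side_R: frozenset[str]
    side_S: frozenset[str]
    bin_index: int

    @property
    def edge_id(self) -> int:
        return self.edge_ids[0]


class Phylogeny:
    """A parsed tree with stable integer edge ids and tip-set bipartitions."""

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")

        # Deterministic preorder edge numbering; the root carries no edge.
        self.tips: list[str] = []
        self._edge_clades: list[frozenset[str]] = []  # edge id -> child-side tip set
        self._clade_of_node: dict[int, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._clade_of_node[id(node)] = frozenset([node.taxon.label])
            else:
                self._clade_of_node[id(node)] = frozenset(
                    itertools.chain.from_iterable(
                        self._clade_of_node[id(c)] for c in node.child_nodes()
                    )
                )
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                self.tips.append(node.taxon.label)
            if node.parent_node is not None:
                self._edge_clades.append(self._clade_of_node[id(node)])
        self.tip_set = frozenset(self.tips)
        self._bipartitions = self._merge_bipartitions()
        # Rooted clades (child-side tip sets); a "remainder" side spanning
        # the root is paraphyletic even though it is a bipartition side.
        self._clade_sides = frozenset(self._edge_clades)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"malformed or duplicate-labeled Newick: {exc}") from exc
        return cls(tree)

    def _merge_bipartitions(self) -> list[EdgeBipartition]:
        groups: dict[frozenset[frozenset[str]], list[int]] = {}
        order: list[frozenset[frozenset[str]]] = []
        for edge_id, clade in enumerate(self._edge_clades):
            other = self.tip_set - clade
            if not other:  # edge below the root when root has a single child
                continue
            key = frozenset([clade, other])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(edge_id)
        out = []
        for key in order:
            ids = tuple(sorted(groups[key]))
            clade = self._edge_clades[ids[0]]
            out.append(EdgeBipartition(ids, clade, self.tip_set - clade))
        return out

    # -- queries --------------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def bipartitions(self) -> list[EdgeBipartition]:
        """Distinct unrooted bipartitions, one per edge (chains merged)."""
        return list(self._bipartitions)

    def is_clade(self, members: frozenset[str]) -> bool:
        """True if ``members`` is a clade of the tree as rooted when parsed."""
        return members in self._clade_sides or members == self.tip_set

    def rooted_clades(self) -> list[frozenset[str]]:
        """Child-side tip sets of all edges, in edge-id order (rooted view)."""
        return list(self._edge_clades)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path) -> Phylogeny:
    """Parse a Newick file; polytomies and internal labels are allowed."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    return Phylogeny(tree)


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Induced tree on ``keep``; degree-2 internal nodes are suppressed."""
    keep = frozenset(keep)
    unknown = keep - tree.tip_set
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    pruned = tree._tree.extract_tree_with_taxa_labels(labels=keep)
    return Phylogeny(pruned)


def edge_bipartitions(tree: Phylogeny) -> list[EdgeBipartition]:
    """One bipartition per edge, tip edges included; an unrooted binary tree
    with D tips yields 2D − 3 of them."""
    return tree.bipartitions()


def rooted_sbp(tree: Phylogeny) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Sequential binary partition read off the rooted tree: one (R, S) row
    per internal node, contrasting its two daughter clades, in preorder.

    A single balance cannot contrast three or more daughter clades, so any
    polytomy (including an unrooted trifurcating root) is a hard error; use
    the edge-wise factorization for unresolved trees.
    """
    rows = []
    for node in tree._tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                "rooted ILR requires a strictly binary rooted tree; node with "
                f"{len(children)} children found (polytomies are not supported)"
            )
        left = tree._clade_of_node[id(children[0])]
        right = tree._clade_of_node[id(children[1])]
        rows.append((left, right))
    if len(rows) != tree.n_tips - 1:
        raise ValueError("rooted SBP must have D - 1 rows; tree is not binary")
    return rows


def split_bin(bin_: TaxonBin, side_R, side_S, tree: Phylogeny, factor_index: int = 0
              ) -> tuple[TaxonBin, TaxonBin]:
    """Cut a bin into the two sides of a partition restricted to it."""
    side_R, side_S = frozenset(side_R), frozenset(side_S)
    if not side_R or not side_S:
        raise ValueError("both sides of the split must be nonempty")
    if side_R | side_S != bin_.members or side_R & side_S:
        raise ValueError("split sides must partition the bin")
    origin = bin_.origin + (factor_index,)
    return (
        TaxonBin(side_R, tree.is_clade(side_R), origin),
        TaxonBin(side_S, tree.is_clade(side_S), origin),
    )


def candidate_partitions(
    bins: list[TaxonBin], tree: Phylogeny, used_edges: set[int]
) -> list[CandidatePartition]:
    """Distinct bin splits induced by unused tree edges.

    For each bin with two or more members, every unused edge whose bipartition
    cuts the bin into two nonempty parts contributes a candidate; edges that
    induce the same cut of the same bin (chains collapsed by earlier splits)
    are merged into one candidate carrying all their ids.  Within each
    candidate, side R is the side *not* containing the lexicographically
    smallest taxon of the bin, fixing the sign of the balance.
    """
    out: list[CandidatePartition] = []
    for b_idx, bin_ in enumerate(bins):
        if len(bin_.members) < 2:
            continue
        anchor = min(bin_.members)
        seen: dict[frozenset[str], list[int]] = {}
        order: list[frozenset[str]] = []
        for bp in tree.bipartitions():
            ids = [e for e in bp.edge_ids if e not in used_edges]
            if not ids:
                continue
            inside_R = bp.side_R & bin_.members
            inside_S = bp.side_S & bin_.members
            if not inside_R or not inside_S:
                continue
            r_side = inside_S if anchor in inside_R else inside_R
            if r_side not in seen:
                seen[r_side] = []
                order.append(r_side)
            seen[r_side].extend(ids)
        for r_side in order:
            ids = tuple(sorted(set(seen[r_side])))
            out.append(CandidatePartition(ids, r_side, bin_.members - r_side, b_idx))
    return out


def enumerate_unrooted_topologies(labels: list[str]):
    """Yield Newick strings for every unrooted binary topology on ``labels``.

    There are (2D − 5)!! topologies for D tips; each is written rooted at the
    internal node adjacent to the first label (a trifurcation), which is the
    canonical unrooted representation.
    """
    if len(labels) < 3:
        if len(labels) == 2:
            yield f"({labels[0]},{labels[1]});"
            return
        raise ValueError("need at least 2 labels")

    def attach(t, x):
        # yield every tree formed by subdividing one edge of t with leaf x
        yield (t, x)
        if isinstance(t, tuple):
            for s in attach(t[0], x):
                yield (s, t[1])
            for s in attach(t[1], x):
                yield (t[0], s)

    def grow(t, rest):
        if not rest:
            yield t
            return
        for s in attach(t, rest[0]):
            yield from grow(s, rest[1:])

    def to_newick(t):
        if isinstance(t, tuple):
            return f"({to_newick(t[0])},{to_newick(t[1])})"
        return t

    first, second, *rest = labels
    for t in grow(second, tuple(rest)):
        if isinstance(t, tuple):
            yield f"({first},{to_newick(t[0])},{to_newick(t[1])});"
        else:
            yield f"({first},{t});"
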