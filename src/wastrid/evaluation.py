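"""Topological comparison of trees: bipartitions, RF, nRF, and the
dataset-level summaries used to characterize simulated conditions.

A bipartition is the split of the leaf set induced by deleting one edge of
the unrooted tree; splits from leaf-incident edges are trivial (present in
every tree on the leaf set) and are excluded everywhere.  The
Robinson-Foulds (RF) distance is the size of the symmetric difference of
the two trees' non-trivial bipartition sets; the normalized RF (nRF) rate
divides by the total number of non-trivial bipartitions in the two trees,
which for two binary trees equals 2n - 6 and makes nRF coincide with the
missing-branch rate.
"""

from __future__ import annotations

from typing import Sequence

from .tree_model import Tree, TreeValidationError

__all__ = [
    "bipartitions",
    "rf_distance",
    "nrf",
    "gene_tree_error",
    "average_discordance",
    "ils_band",
]


def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial bipartitions of the unrooted tree.

    Each split is canonically encoded as the frozenset of leaf labels on
    the side *not* containing a fixed reference taxon (the lexicographically
    smallest label), which makes the encoding independent of rooting.
    """
    t = tree.unrooted_copy()
    all_leaves = frozenset(t.leaf_labels())
    if len(all_leaves) != t.n_leaves:
        raise TreeValidationError("duplicate leaf labels")
    ref = min(all_leaves)
    splits: set[frozenset] = set()
    below: dict[int, frozenset] = {}
    for node in t.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
            continue
        side = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = side
        if node.parent is None:
            continue  # root "edge" is not an edge of the unrooted tree
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue  # trivial
        splits.add(side if ref not in side else all_leaves - side)
    return splits


def _require_same_leaves(T1: Tree, T2: Tree) -> None:
    l1, l2 = set(T1.leaf_labels()), set(T2.leaf_labels())
    if l1 != l2:
        only1 = sorted(l1 - l2)[:5]
        only2 = sorted(l2 - l1)[:5]
        raise TreeValidationError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )


def rf_distance(T1: Tree, T2: Tree) -> int:
    """Robinson-Foulds distance over non-trivial bipartitions."""
    _require_same_leaves(T1, T2)
    return len(bipartitions(T1) ^ bipartitions(T2))


def nrf(T1: Tree, T2: Tree) -> float:
    """RF normalized by the total non-trivial bipartition count.

    For two binary n-leaf trees the denominator is 2n - 6; for partially
    resolved trees it is the sum of the two trees' non-trivial bipartition
    counts.  Two star trees (denominator 0) are identical, giving 0.
    """
    _require_same_leaves(T1, T2)
    b1, b2 = bipartitions(T1), bipartitions(T2)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


def _restricted_nrf(T1: Tree, T2: Tree) -> float:
    shared = set(T1.leaf_labels()) & set(T2.leaf_labels())
    if len(shared) < 4:
        raise TreeValidationError(
            f"fewer than 4 shared leaves ({len(shared)}); nRF undefined"
        )
    a = T1 if set(T1.leaf_labels()) == shared else T1.restrict_to(shared)
    b = T2 if set(T2.leaf_labels()) == shared else T2.restrict_to(shared)
    return nrf(a, b)


def gene_tree_error(true_trees: Sequence[Tree], est_trees: Sequence[Tree]) -> float:
    """GTEE: mean nRF between paired true and estimated gene trees.

    When a pair's leaf sets differ (incomplete gene trees), both trees are
    restricted to the shared leaves before comparing.
    """
    if not true_trees or len(true_trees) != len(est_trees):
        raise ValueError("need non-empty paired lists of equal length")
    vals = [_restricted_nrf(t, e) for t, e in zip(true_trees, est_trees)]
    return sum(vals) / len(vals)


def average_discordance(species_tree: Tree, gene_trees: Sequence[Tree]) -> float:
    """AD: mean nRF between the species tree and each gene tree.

    This is the standard proxy for the level of incomplete lineage sorting
    in a simulated condition.
    """
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    vals = [_restricted_nrf(species_tree, g) for g in gene_trees]
    return sum(vals) / len(vals)


def ils_band(ad_percent: float) -> str:
    """Categorical ILS level from the AD percentage.

    Below 25% is low (L), up to but not including 40% is medium (M), up to
    but not including 60% is high (H), and anything above is very high
    (VH).  Values in the 25-26% seam are assigned to M.
    """
    if ad_percent < 0 or ad_percent > 100:
        raise ValueError("AD percentage must be in [0, 100]")
    if ad_percent < 25.0:
        return "L"
    if ad_percent < 40.0:
        return "M"
    if ad_percent < 60.0:
        return "H"
    return "VH"
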