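"""Imputation of incomplete average-distance matrices.

When some taxon pair co-occurs in no gene tree, its average distance is
undefined and the BME search cannot run.  The two-stage completion used
here fills the gaps from tree structure rather than from an arbitrary
constant:

(a) run UPGMA* — UPGMA restricted to cluster pairs that have at least one
    *defined* inter-cluster distance, averaging only over the defined
    pairs — on the masked matrix, giving a tree U1;
(b) complete the matrix by copying, for each missing pair, the topological
    (edge-count) path length between the pair's leaves in U1, giving D1;
(c) run an NNI-only BME search on D1, giving a tree U2, and complete the
    original matrix again from U2's path lengths, giving D2.

Originally defined entries are never altered: D1 and D2 agree with D
wherever D was defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components

from .bme_engine import (
    ScoredTree,
    SearchConfig,
    adjacency_for_tree,
    leaf_topological_distances,
    search,
)
from .tree_model import Node, Tree
from .weighted_distance import AverageMatrix

__all__ = [
    "CompletionResult",
    "DisconnectedTaxaError",
    "upgma_star",
    "topological_paths",
    "complete_matrix",
    "two_stage_completion",
]


class DisconnectedTaxaError(ValueError):
    """The definedness graph over taxa is disconnected.

    No sequence of valid UPGMA* joins can cover all taxa, and no principled
    distance exists between the components.
    """

    def __init__(self, components: list[list[str]]) -> None:
        self.components = components
        preview = "; ".join(
            "{" + ", ".join(c[:5]) + (", ..." if len(c) > 5 else "") + "}"
            for c in components
        )
        super().__init__(
            f"definedness graph has {len(components)} components: {preview}"
        )


def _check_connected(avg: AverageMatrix) -> None:
    defined = (avg.counts > 0).astype(np.int8)
    n_comp, labels = connected_components(defined, directed=False)
    if n_comp > 1:
        comps: list[list[str]] = [[] for _ in range(n_comp)]
        for i, c in enumerate(labels):
            comps[c].append(avg.labels[i])
        raise DisconnectedTaxaError(comps)


def upgma_star(avg: AverageMatrix) -> Tree:
    """Agglomerative UPGMA variant tolerating missing entries.

    Two clusters are joinable only if some cross pair has a defined
    distance; the inter-cluster distance is the arithmetic mean of the
    defined cross-pair distances (a plain mean over pairs, not a weighted
    mean of sub-cluster averages).  The joinable pair with the smallest
    average is merged; ties break lexicographically on the clusters'
    smallest member indices.  Returns the rooted join tree with ultrametric
    branch lengths (heights = half the joining distance, floored at the
    children's heights so reversals cannot produce negative branches).

    On a complete matrix every pair is joinable and this reduces exactly to
    classic average-linkage UPGMA.
    """
    _check_connected(avg)
    n = avg.n
    D = np.where(avg.counts > 0, avg.sums / np.maximum(avg.counts, 1), 0.0)
    defined = (avg.counts > 0).astype(float)
    np.fill_diagonal(defined, 0.0)

    if n == 1:
        return Tree(Node(label=avg.labels[0]))

    # pair-sums and pair-counts between active clusters
    PS = D * defined
    PC = defined.copy()
    nodes: list[Optional[Node]] = [Node(label=lab) for lab in avg.labels]
    heights = [0.0] * n
    reps = list(range(n))  # smallest registry index per cluster
    active = list(range(n))

    while len(active) > 1:
        best: Optional[tuple[float, int, int, int, int]] = None
        for ai in range(len(active)):
            i = active[ai]
            for bi in range(ai + 1, len(active)):
                j = active[bi]
                if PC[i, j] <= 0:
                    continue
                d = PS[i, j] / PC[i, j]
                r1, r2 = sorted((reps[i], reps[j]))
                key = (d, r1, r2, i, j)
                if best is None or key < best:
                    best = key
        if best is None:
            # unreachable after the connectivity check, but be defensive
            raise DisconnectedTaxaError([[avg.labels[reps[i]]] for i in active])
        d, _, _, i, j = best
        parent = Node()
        h = max(d / 2.0, heights[i], heights[j])
        for child_idx in (i, j):
            child = nodes[child_idx]
            child.length = h - heights[child_idx]
            parent.add_child(child)
        # merge j into i (Lance-Williams-style update on sums and counts)
        PS[i, :] += PS[j, :]
        PS[:, i] = PS[i, :]
        PC[i, :] += PC[j, :]
        PC[:, i] = PC[i, :]
        PS[i, i] = PC[i, i] = 0.0
        nodes[i] = parent
        heights[i] = h
        reps[i] = min(reps[i], reps[j])
        nodes[j] = None
        active.remove(j)

    return Tree(nodes[active[0]])


def topological_paths(tree: Tree, labels: list[str]) -> np.ndarray:
    """Edge-count leaf-to-leaf distances, rows/columns in ``labels`` order.

    Any degree-2 root is suppressed before counting, so the result depends
    only on the unrooted topology.
    """
    adj = adjacency_for_tree(tree, labels)
    return leaf_topological_distances(adj, len(labels)).astype(float)


def complete_matrix(avg: AverageMatrix, A: np.ndarray) -> np.ndarray:
    """Copy defined entries of the average matrix, fill the rest from A."""
    if A.shape != (avg.n, avg.n):
        raise ValueError("fill matrix has the wrong shape")
    D = avg.D
    out = np.where(avg.mask, A, D)
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class CompletionResult:
    """All intermediates of the two-stage completion, for inspection."""

    U1: Tree
    A1: np.ndarray
    D1: np.ndarray
    U2: Tree
    A2: np.ndarray
    D2: np.ndarray


def two_stage_completion(
    avg: AverageMatrix,
    config: SearchConfig = SearchConfig(),
) -> CompletionResult:
    """UPGMA* fill, NNI-only BME refinement, second fill.

    Precondition: the matrix has at least one missing entry (a complete
    matrix needs no imputation and the pipeline bypasses this step) and the
    definedness graph is connected.
    """
    U1 = upgma_star(avg)
    A1 = topological_paths(U1, avg.labels)
    D1 = complete_matrix(avg, A1)
    nni_cfg = SearchConfig(
        moves="nni_only",
        max_iterations=config.max_iterations,
        rel_tolerance=config.rel_tolerance,
        insertion_order=config.insertion_order,
        seed=config.seed,
    )
    scored = search(D1, nni_cfg, labels=avg.labels)
    U2 = scored.to_tree(avg.labels)
    A2 = topological_paths(U2, avg.labels)
    D2 = complete_matrix(avg, A2)
    return CompletionResult(U1=U1, A1=A1, D1=D1, U2=U2, A2=A2, D2=D2)
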