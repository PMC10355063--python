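"""Shared fixtures: random annotated trees and independent oracles.

The oracles here deliberately take different algorithmic routes from the
package (per-leaf Dijkstra over an explicit graph, explicit split-set
comparison, literal double loops) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import collections

import numpy as np
import pytest

from wastrid.tree_model import Node, Tree, TaxonRegistry, to_adjacency


def random_annotated_tree(
    rng: np.random.Generator,
    n_leaves: int,
    polytomy_prob: float = 0.0,
    labels=None,
) -> Tree:
    """Random rooted tree with lengths and internal supports.

    Built by random sequential attachment; with probability
    ``polytomy_prob`` a new leaf is attached to an existing internal node
    (creating/growing a polytomy) instead of subdividing an edge.
    """
    if labels is None:
        labels = [f"t{i}" for i in range(n_leaves)]
    root = Node()
    a, b = Node(label=labels[0]), Node(label=labels[1])
    root.add_child(a)
    root.add_child(b)
    tree = Tree(root)
    for lab in labels[2:]:
        nodes = [v for v in tree.preorder() if v is not root]
        internals = [v for v in tree.preorder() if not v.is_leaf]
        if internals and rng.random() < polytomy_prob:
            host = internals[rng.integers(len(internals))]
            host.add_child(Node(label=lab))
        else:
            target = nodes[rng.integers(len(nodes))]
            parent = target.parent
            mid = Node()
            idx = parent.children.index(target)
            parent.children[idx] = mid
            mid.parent = parent
            mid.add_child(target)
            mid.add_child(Node(label=lab))
    for v in tree.preorder():
        if v is root:
            continue
        v.length = float(0.05 + rng.exponential(0.5))
        if not v.is_leaf:
            v.support = float(rng.uniform(0.0, 1.0))
    return tree


def oracle_path_sums(tree: Tree, weight_of) -> dict[frozenset, float]:
    """Per-leaf-pair path sums by Dijkstra on an explicit graph.

    ``weight_of(u, v, attrs)`` maps an edge to its weight.  Works on the
    unrooted view (degree-2 root suppressed), independent of the package's
    post-order algorithm.
    """
    import networkx as nx

    adj, attrs, leaf_names = to_adjacency(tree)
    g = nx.Graph()
    for u in adj:
        for v in adj[u]:
            if u < v:
                g.add_edge(u, v, weight=weight_of(u, v, attrs[frozenset((u, v))], adj))
    out = {}
    leaves = sorted(leaf_names)
    for i, u in enumerate(leaves):
        dist = nx.single_source_dijkstra_path_length(g, u)
        for v in leaves[i + 1 :]:
            out[frozenset((leaf_names[u], leaf_names[v]))] = dist[v]
    return out


def additive_matrix_for(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Weighted leaf-to-leaf path-length matrix by BFS (the additive matrix)."""
    adj, attrs, leaf_names = to_adjacency(tree)
    n = len(leaf_names)
    labels = [leaf_names[i] for i in range(n)]
    D = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        dq = collections.deque([s])
        while dq:
            v = dq.popleft()
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + attrs[frozenset((u, v))]["length"]
                    dq.append(u)
        D[s] = [dist[j] for j in range(n)]
    np.fill_diagonal(D, 0.0)
    return D, labels


def same_unrooted_topology(t1: Tree, t2: Tree) -> bool:
    from wastrid.evaluation import rf_distance

    return rf_distance(t1, t2) == 0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
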