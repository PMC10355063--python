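"""Balanced minimum evolution (BME) tree search.

Given a complete symmetric distance matrix D, the BME criterion selects the
binary unrooted topology T minimizing the Pauplin length

    L(T) = sum over u < v of 2^(1 - p_uv) D[u, v],

where p_uv is the topological (edge-count) distance between leaves u and v
in T.  On an additive matrix the Pauplin length equals the total branch
length of the generating tree and is uniquely minimized by its topology, so
a steepest-descent search started near the truth recovers it exactly — the
"safety radius" behaviour the overall pipeline relies on.

The search mirrors the classical heuristic: a greedy insertion starting
tree, then nearest-neighbour-interchange (NNI) steepest descent, optionally
interleaved with subtree-prune-and-regraft (SPR) passes.  Moves are scored
by full O(n^2) rescoring, which keeps the engine simple and exactly
consistent with :func:`pauplin_length`; at the problem sizes this package
targets the extra constant factor is immaterial.

Topologies are manipulated as adjacency maps ``{node: [neighbors]}`` with
leaves numbered 0..n-1 (matrix order) and internal nodes from n upward.
All candidate enumeration is in sorted node order, so the search is fully
deterministic for a given matrix and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Optional, Sequence

import numpy as np

from .tree_model import Tree, from_adjacency

__all__ = [
    "SearchConfig",
    "ScoredTree",
    "pauplin_length",
    "bme_score",
    "leaf_topological_distances",
    "greedy_bme",
    "bnni",
    "bspr",
    "search",
    "enumerate_topologies",
    "adjacency_for_tree",
]

Adjacency = dict[int, list[int]]


@dataclass(frozen=True)
class SearchConfig:
    """Search-strategy knobs.

    ``moves`` selects NNI-only or the accurate NNI+SPR schedule (default);
    ``rel_tolerance`` is the minimum score decrease, relative to the current
    score, for a move to be accepted; ``insertion_order`` is either
    ``"matrix_order"`` or ``"random"`` (seeded) for the greedy start.
    """

    moves: str = "nni_and_spr"
    max_iterations: int = 10_000
    rel_tolerance: float = 1e-10
    insertion_order: str = "matrix_order"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moves not in ("nni_only", "nni_and_spr"):
            raise ValueError(f"unknown move set {self.moves!r}")
        if self.insertion_order not in ("matrix_order", "random"):
            raise ValueError(f"unknown insertion order {self.insertion_order!r}")
        if self.rel_tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ScoredTree:
    """A binary unrooted topology with its Pauplin length."""

    adjacency: Adjacency
    balanced_length: float
    n_leaves: int
    hit_iteration_cap: bool = False

    def to_tree(self, labels: Optional[Sequence[str]] = None) -> Tree:
        names = (
            {i: labels[i] for i in range(self.n_leaves)}
            if labels is not None
            else {i: str(i) for i in range(self.n_leaves)}
        )
        return from_adjacency(self.adjacency, leaf_names=names)


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------


def _postorder_edges(adj: Adjacency, root: int) -> list[tuple[int, int]]:
    """(node, parent) pairs in an order where children precede parents."""
    order = []
    stack = [(root, -1)]
    while stack:
        v, p = stack.pop()
        order.append((v, p))
        for u in adj[v]:
            if u != p:
                stack.append((u, v))
    order.reverse()
    return order


def bme_score(adj: Adjacency, D: np.ndarray, n: int) -> float:
    """Pauplin length of the topology ``adj`` under matrix ``D``.

    Single post-order pass: each node carries (leaf ids, 2^-depth weights);
    at each internal node the pairwise child combination contributes
    2 * w_A^T D[A, B] w_B, which is exactly sum 2^(1-p_uv) D[u, v] over the
    pairs meeting there.
    """
    if n == 2:
        return float(D[0, 1])
    root = next(v for v in adj if len(adj[v]) > 1)
    score = 0.0
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for v, p in _postorder_edges(adj, root):
        if len(adj[v]) == 1:
            carry[v] = (np.array([v], dtype=np.intp), np.array([1.0]))
            continue
        parts = []
        for u in adj[v]:
            if u == p:
                continue
            ids, w = carry.pop(u)
            parts.append((ids, w * 0.5))
        for (ia, wa), (ib, wb) in combinations(parts, 2):
            score += 2.0 * float(wa @ D[np.ix_(ia, ib)] @ wb)
        carry[v] = (
            np.concatenate([q[0] for q in parts]),
            np.concatenate([q[1] for q in parts]),
        )
    return score


def leaf_topological_distances(adj: Adjacency, n: int) -> np.ndarray:
    """Edge-count distances p_uv between all leaf pairs of ``adj``."""
    P = np.zeros((n, n), dtype=np.int64)
    if n < 2:
        return P
    if n == 2:
        P[0, 1] = P[1, 0] = 1
        return P
    root = next(v for v in adj if len(adj[v]) > 1)
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for v, p in _postorder_edges(adj, root):
        if len(adj[v]) == 1:
            carry[v] = (np.array([v], dtype=np.intp), np.zeros(1, dtype=np.int64))
            continue
        parts = []
        for u in adj[v]:
            if u == p:
                continue
            ids, d = carry.pop(u)
            parts.append((ids, d + 1))
        for (ia, da), (ib, db) in combinations(parts, 2):
            block = da[:, None] + db[None, :]
            P[np.ix_(ia, ib)] = block
            P[np.ix_(ib, ia)] = block.T
        carry[v] = (
            np.concatenate([q[0] for q in parts]),
            np.concatenate([q[1] for q in parts]),
        )
    return P


def pauplin_length(tree: Tree | Adjacency, D: np.ndarray, labels: Optional[Sequence[str]] = None) -> float:
    """Pauplin length of a binary unrooted tree under ``D``.

    Accepts either a :class:`~wastrid.tree_model.Tree` (leaves matched to
    ``labels``, defaulting to D's row order being the tree's sorted leaf
    labels) or a raw adjacency map.
    """
    n = D.shape[0]
    if isinstance(tree, dict):
        adj = tree
    else:
        adj = adjacency_for_tree(tree, labels)
    _check_binary(adj, n)
    return bme_score(adj, D, n)


def adjacency_for_tree(tree: Tree, labels: Optional[Sequence[str]] = None) -> Adjacency:
    """Adjacency of ``tree`` with leaves renumbered to match ``labels``."""
    from .tree_model import to_adjacency

    adj, _, leaf_names = to_adjacency(tree)
    if labels is None:
        labels = sorted(leaf_names.values())
    want = {lab: i for i, lab in enumerate(labels)}
    if set(leaf_names.values()) != set(want):
        raise ValueError("tree leaves do not match the provided labels")
    # to_adjacency numbers leaves 0..n-1 and internals from n up, so only
    # the leaves need renumbering to match the matrix order
    relabel = {old: want[lab] for old, lab in leaf_names.items()}
    relabel.update({v: v for v in adj if len(adj[v]) > 1})
    return {relabel[v]: [relabel[u] for u in nbrs] for v, nbrs in adj.items()}


def _check_binary(adj: Adjacency, n: int) -> None:
    for v, nbrs in adj.items():
        deg = len(nbrs)
        if deg not in (1, 3) and len(adj) > 2:
            raise ValueError(
                f"tree is not binary/unrooted: node {v} has degree {deg}"
            )


# --------------------------------------------------------------------------
# Topology editing primitives
# --------------------------------------------------------------------------


def _copy(adj: Adjacency) -> Adjacency:
    return {v: list(nbrs) for v, nbrs in adj.items()}


def _replace(adj: Adjacency, v: int, old: int, new: int) -> None:
    adj[v][adj[v].index(old)] = new


def _insert_leaf(adj: Adjacency, leaf: int, edge: tuple[int, int], new_internal: int) -> Adjacency:
    u, v = edge
    out = _copy(adj)
    _replace(out, u, v, new_internal)
    _replace(out, v, u, new_internal)
    out[new_internal] = [u, v, leaf]
    out[leaf] = [new_internal]
    return out


def _edges(adj: Adjacency) -> list[tuple[int, int]]:
    return sorted(
        (min(u, v), max(u, v)) for u in adj for v in adj[u] if u < v
    )


def _internal_edges(adj: Adjacency, n: int) -> list[tuple[int, int]]:
    return [(u, v) for (u, v) in _edges(adj) if u >= n and v >= n]


def _nni_moves(adj: Adjacency, n: int) -> Iterator[tuple[tuple[int, int], int]]:
    """All NNI moves as ((internal edge), alternative in {0, 1})."""
    for edge in _internal_edges(adj, n):
        yield edge, 0
        yield edge, 1


def _apply_nni(adj: Adjacency, edge: tuple[int, int], alt: int) -> Adjacency:
    u, v = edge
    a, b = sorted(x for x in adj[u] if x != v)
    c, d = sorted(x for x in adj[v] if x != u)
    swap_with = c if alt == 0 else d
    out = _copy(adj)
    _replace(out, u, b, swap_with)
    _replace(out, v, swap_with, b)
    _replace(out, b, u, v)
    _replace(out, swap_with, v, u)
    return out


def _spr_moves(adj: Adjacency, n: int) -> Iterator[tuple[int, int, tuple[int, int]]]:
    """All SPR moves as (pruned_attach u, cut neighbor v, regraft edge).

    Cutting edge (u, v) detaches the subtree hanging at u; v must be
    internal (it is suppressed and reused as the regraft point).  Regraft
    edges exclude the two edges incident to v (those recreate the original
    topology).
    """
    for u0, v0 in _edges(adj):
        for u, v in ((u0, v0), (v0, u0)):
            if len(adj[v]) == 1:
                continue  # cannot leave a lone leaf behind
            pruned = _component(adj, u, v)
            for e in _edges(adj):
                a, b = e
                if a in pruned or b in pruned:
                    continue
                if v in e:
                    continue  # adjacent edge: regraft recreates the original
                yield u, v, e


def _component(adj: Adjacency, start: int, blocked: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        w = stack.pop()
        for z in adj[w]:
            if z != blocked and z not in seen:
                seen.add(z)
                stack.append(z)
    return seen


def _apply_spr(adj: Adjacency, u: int, v: int, regraft: tuple[int, int]) -> Adjacency:
    out = _copy(adj)
    x, y = (w for w in out[v] if w != u)
    # detach: suppress v, connect x-y
    _replace(out, x, v, y)
    _replace(out, y, v, x)
    # regraft: subdivide edge (a, b) with v, keeping v's link to u
    a, b = regraft
    _replace(out, a, b, v)
    _replace(out, b, a, v)
    out[v] = [a, b, u]
    return out


# --------------------------------------------------------------------------
# Search stages
# --------------------------------------------------------------------------


def greedy_bme(D: np.ndarray, config: SearchConfig = SearchConfig()) -> ScoredTree:
    """Greedy taxon-insertion starting tree.

    Starts from the unique unrooted tree on the first three taxa and inserts
    each remaining taxon on the edge whose subdivision minimizes the Pauplin
    length of the enlarged tree; ties go to the earliest edge in sorted
    order.
    """
    n = D.shape[0]
    _validate_matrix(D)
    if n < 3:
        if n < 2:
            warnings.warn("fewer than 2 taxa; trivial result", stacklevel=2)
            adj: Adjacency = {0: []} if n == 1 else {}
            return ScoredTree(adj, 0.0, n)
        return ScoredTree({0: [1], 1: [0]}, float(D[0, 1]), 2)

    if config.insertion_order == "matrix_order":
        order = list(range(n))
    else:
        rng = np.random.default_rng(config.seed)
        order = list(rng.permutation(n))
    first, rest = order[:3], order[3:]
    hub = n  # internal ids run from n upward
    adj = {hub: list(first)}
    for leaf in first:
        adj[leaf] = [hub]
    next_internal = n + 1
    for leaf in rest:
        best_score, best_adj = np.inf, None
        for edge in _edges(adj):
            cand = _insert_leaf(adj, leaf, edge, next_internal)
            s = bme_score(cand, D, n)
            if s < best_score - 0.0:  # strict improvement; first best kept on ties
                best_score, best_adj = s, cand
        adj = best_adj
        next_internal += 1
    return ScoredTree(adj, bme_score(adj, D, n), n)


def _steepest_nni(
    start: ScoredTree, D: np.ndarray, config: SearchConfig
) -> ScoredTree:
    adj, score = start.adjacency, start.balanced_length
    n = start.n_leaves
    iterations = 0
    capped = False
    while True:
        if iterations >= config.max_iterations:
            warnings.warn("NNI iteration cap reached", stacklevel=3)
            capped = True
            break
        best_delta, best_adj = 0.0, None
        threshold = config.rel_tolerance * max(abs(score), 1.0)
        for edge, alt in _nni_moves(adj, n):
            cand = _apply_nni(adj, edge, alt)
            s = bme_score(cand, D, n)
            delta = score - s
            if delta > threshold and delta > best_delta:
                best_delta, best_adj = delta, cand
        if best_adj is None:
            break
        adj, score = best_adj, score - best_delta
        iterations += 1
    return ScoredTree(adj, bme_score(adj, D, n), n, hit_iteration_cap=capped)


def bnni(start: ScoredTree, D: np.ndarray, config: SearchConfig = SearchConfig()) -> ScoredTree:
    """Steepest-descent NNI to a local optimum of the Pauplin length."""
    return _steepest_nni(start, D, config)


def bspr(start: ScoredTree, D: np.ndarray, config: SearchConfig = SearchConfig()) -> ScoredTree:
    """NNI-to-convergence interleaved with single steepest SPR passes.

    Schedule: run NNI to a local optimum, then scan every prune/regraft
    pair once and apply the best strictly improving one; repeat until no
    SPR improves.
    """
    n = start.n_leaves
    current = _steepest_nni(start, D, config)
    iterations = 0
    while True:
        if iterations >= config.max_iterations:
            warnings.warn("SPR iteration cap reached", stacklevel=2)
            current.hit_iteration_cap = True
            break
        adj, score = current.adjacency, current.balanced_length
        threshold = config.rel_tolerance * max(abs(score), 1.0)
        best_delta, best_adj = 0.0, None
        for u, v, e in _spr_moves(adj, n):
            cand = _apply_spr(adj, u, v, e)
            s = bme_score(cand, D, n)
            delta = score - s
            if delta > threshold and delta > best_delta:
                best_delta, best_adj = delta, cand
        if best_adj is None:
            break
        improved = ScoredTree(best_adj, score - best_delta, n)
        current = _steepest_nni(improved, D, config)
        iterations += 1
    return ScoredTree(
        current.adjacency,
        bme_score(current.adjacency, D, n),
        n,
        hit_iteration_cap=current.hit_iteration_cap,
    )


def search(
    D: np.ndarray,
    config: SearchConfig = SearchConfig(),
    labels: Optional[Sequence[str]] = None,
) -> ScoredTree:
    """Full BME search: greedy start, NNI descent, optional SPR passes."""
    _validate_matrix(D)
    start = greedy_bme(D, config)
    if start.n_leaves < 4:
        return start
    if config.moves == "nni_only":
        return bnni(start, D, config)
    return bspr(start, D, config)


def _validate_matrix(D: np.ndarray) -> None:
    D = np.asarray(D)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(D)):
        raise ValueError("distance matrix has undefined entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")


# --------------------------------------------------------------------------
# Exhaustive enumeration (oracle-scale only)
# --------------------------------------------------------------------------


def enumerate_topologies(n: int) -> Iterator[Adjacency]:
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1.

    Recursive leaf insertion; intended for oracle checks at n <= ~8.
    """
    if n < 3:
        raise ValueError("enumeration needs n >= 3")

    base: Adjacency = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}

    def grow(adj: Adjacency, leaf: int, next_internal: int) -> Iterator[Adjacency]:
        if leaf == n:
            yield adj
            return
        for edge in _edges(adj):
            cand = _insert_leaf(adj, leaf, edge, next_internal)
            yield from grow(cand, leaf + 1, next_internal + 1)

    yield from grow(base, 3, n + 1)
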