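"""Weighted intertaxon distances per gene tree and their average matrix.

For a gene tree G and leaves u, v, the intertaxon distance is

    d_G(u, v) = sum over edges e on the u-v path of w(e)

where the edge weight w(e) depends on the active mode:

* ``unweighted`` — w(e) = 1, the classical edge-count internode distance;
* ``support``    — w(e) = s(e), the branch support in [0, 1], with
  leaf-incident edges fixed at 1 (a leaf edge is always "correct");
* ``pathlength`` — w(e) = l(e), the branch length, optionally divided by
  the gene tree's branch-length diameter (max leaf-to-leaf path sum).

Averaging over the gene set gives the matrix handed to the tree search:
D[u, v] is the mean of d_G(u, v) over the genes containing both u and v;
pairs co-occurring in no gene are marked missing, not zero.

All tables are computed by a single post-order traversal per gene that
maintains, for each visited node, the vector of accumulated weights to the
leaves below it and combines child vectors pairwise, so a gene with m
leaves costs O(m^2) — each leaf pair is touched exactly once, at the node
where the two leaves' paths meet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .tree_model import Node, TaxonRegistry, Tree, TreeValidationError

__all__ = [
    "EdgeWeightMode",
    "PairDistanceTable",
    "AverageMatrix",
    "edge_weight",
    "gene_scale",
    "per_gene_distances",
    "accumulate",
    "average_matrix",
    "write_phylip",
    "read_phylip",
]

_MODES = ("unweighted", "support", "pathlength")
_NORMALIZATIONS = ("none", "max_path")


@dataclass(frozen=True)
class EdgeWeightMode:
    """Which per-edge weight defines the intertaxon distance."""

    mode: str = "support"
    normalization: str = "none"  # pathlength mode only

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {_NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )


@dataclass
class PairDistanceTable:
    """Symmetric weighted path-sum table over one gene's leaf set.

    ``leaf_indices[i]`` is the registry index of the gene-local leaf ``i``;
    ``table[i, j]`` is d_G between those leaves.
    """

    gene_index: int
    leaf_indices: np.ndarray  # (m,) registry indices, ascending
    table: np.ndarray  # (m, m) float

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)


@dataclass
class AverageMatrix:
    """Averaged intertaxon distances with per-pair gene counts.

    ``D[u, v]`` is defined only where ``counts[u, v] > 0``; elsewhere it is
    NaN and ``mask`` is True.
    """

    sums: np.ndarray
    counts: np.ndarray
    labels: list[str]

    @property
    def n(self) -> int:
        return self.sums.shape[0]

    @property
    def mask(self) -> np.ndarray:
        m = self.counts == 0
        np.fill_diagonal(m, False)
        return m

    @property
    def D(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = self.sums / self.counts
        d[self.mask] = np.nan
        np.fill_diagonal(d, 0.0)
        return d

    @property
    def n_missing_pairs(self) -> int:
        return int(np.sum(self.mask) // 2)

    @property
    def is_complete(self) -> bool:
        return self.n_missing_pairs == 0


def edge_weight(node: Node, mode: EdgeWeightMode, gene_scale_value: float = 1.0) -> float:
    """Weight of the edge above ``node`` under ``mode``.

    The edge is leaf-incident iff ``node`` is a leaf (the stored root is
    suppressed before this is called, so every parent is internal in the
    unrooted sense).
    """
    if mode.mode == "unweighted":
        return 1.0
    if mode.mode == "support":
        if node.is_leaf:
            return 1.0
        if node.support is None:
            raise TreeValidationError(
                f"support mode requires normalized supports; edge above "
                f"{_edge_name(node)} has none"
            )
        return float(node.support)
    # pathlength
    if node.length is None:
        raise TreeValidationError(
            f"pathlength mode requires branch lengths; edge above "
            f"{_edge_name(node)} has none"
        )
    return float(node.length) / gene_scale_value


def _edge_name(node: Node) -> str:
    if node.is_leaf:
        return f"leaf {node.label!r}"
    labs = []
    stack = [node]
    while stack and len(labs) < 3:
        v = stack.pop()
        if v.is_leaf:
            labs.append(v.label)
        else:
            stack.extend(v.children)
    return f"clade containing {labs}"


def gene_scale(tree: Tree, normalization: str = "max_path") -> float:
    """Branch-length diameter of the gene tree (or 1.0 for ``none``).

    The diameter — the maximum over leaf pairs of the path-length sum — is
    found by the two-sweep farthest-leaf search: from an arbitrary leaf find
    the farthest leaf a, then the farthest leaf from a; both sweeps are
    single traversals, so the whole computation is O(n).
    """
    if normalization == "none":
        return 1.0
    if normalization != "max_path":
        raise ValueError(f"unknown normalization {normalization!r}")
    t = tree.unrooted_copy()
    leaves = t.leaves()
    if len(leaves) < 2:
        raise TreeValidationError("diameter undefined for < 2 leaves")

    def farthest_from(start: Node) -> tuple[Node, float]:
        best, best_d = start, 0.0
        stack = [(start, None, 0.0)]
        while stack:
            node, came_from, dist = stack.pop()
            if node.is_leaf and dist > best_d:
                best, best_d = node, dist
            neighbors = list(node.children)
            if node.parent is not None:
                neighbors.append(node.parent)
            for nb in neighbors:
                if nb is came_from:
                    continue
                edge_len = nb.length if nb.parent is node else node.length
                if edge_len is None:
                    raise TreeValidationError(
                        "pathlength mode requires branch lengths on every edge"
                    )
                stack.append((nb, node, dist + edge_len))
        return best, best_d

    a, _ = farthest_from(leaves[0])
    _, diameter = farthest_from(a)
    if diameter <= 0.0:
        raise TreeValidationError(
            "gene tree has zero branch-length diameter; cannot normalize"
        )
    return diameter


def per_gene_distances(
    tree: Tree,
    mode: EdgeWeightMode,
    registry: TaxonRegistry,
    gene_index: int = 0,
) -> PairDistanceTable:
    """All-pairs weighted path sums for one gene tree.

    One post-order traversal: each node carries (leaf ids, accumulated
    weights); at an internal node the child vectors are combined over all
    unordered child pairs (which handles polytomies), writing each leaf
    pair's distance exactly once.
    """
    t = tree.unrooted_copy()
    leaves = t.leaves()
    m = len(leaves)
    if m < 2:
        warnings.warn(
            f"gene {gene_index} has fewer than 2 leaves; empty table",
            stacklevel=2,
        )
        return PairDistanceTable(
            gene_index,
            np.array([registry.index(l.label) for l in leaves], dtype=np.intp),
            np.zeros((m, m)),
        )
    scale = 1.0
    if mode.mode == "pathlength":
        scale = gene_scale(t, mode.normalization)

    reg_idx = np.array(sorted(registry.index(l.label) for l in leaves), dtype=np.intp)
    local = {int(r): i for i, r in enumerate(reg_idx)}
    table = np.zeros((m, m))

    # iterative post-order over the unrooted copy's stored rooting
    order: list[Node] = list(t.preorder())
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in reversed(order):
        if node.is_leaf:
            ids = np.array([local[registry.index(node.label)]], dtype=np.intp)
            acc = np.zeros(1)
        else:
            parts = []
            for child in node.children:
                c_ids, c_acc = carry.pop(id(child))
                w = edge_weight(child, mode, scale)
                parts.append((c_ids, c_acc + w))
            for i in range(len(parts)):
                ids_i, acc_i = parts[i]
                for j in range(i + 1, len(parts)):
                    ids_j, acc_j = parts[j]
                    block = acc_i[:, None] + acc_j[None, :]
                    table[np.ix_(ids_i, ids_j)] = block
                    table[np.ix_(ids_j, ids_i)] = block.T
            ids = np.concatenate([p[0] for p in parts])
            acc = np.concatenate([p[1] for p in parts])
        carry[id(node)] = (ids, acc)
    return PairDistanceTable(gene_index, reg_idx, table)


def accumulate(tables: Iterable[PairDistanceTable], registry: TaxonRegistry) -> AverageMatrix:
    """Sum per-gene tables into an :class:`AverageMatrix`.

    Summation order is the table (gene) order, so results are bitwise
    deterministic for a fixed input order.
    """
    n = len(registry)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for tab in tables:
        idx = tab.leaf_indices
        if len(idx) and idx.max() >= n:
            raise ValueError("table references a taxon outside the registry")
        if len(idx) < 2:
            continue
        sums[np.ix_(idx, idx)] += tab.table
        counts[np.ix_(idx, idx)] += 1
    np.fill_diagonal(sums, 0.0)
    np.fill_diagonal(counts, 0)
    return AverageMatrix(sums=sums, counts=counts, labels=registry.labels)


def average_matrix(
    trees: Sequence[Tree],
    mode: EdgeWeightMode,
    registry: TaxonRegistry,
) -> AverageMatrix:
    """Convenience wrapper: per-gene tables then accumulation."""
    tables = (
        per_gene_distances(t, mode, registry, gene_index=i)
        for i, t in enumerate(trees)
    )
    return accumulate(tables, registry)


def read_phylip(text: str, missing_token: str = "-1") -> tuple[list[str], np.ndarray]:
    """Parse a PHYLIP square distance matrix into (labels, matrix).

    Entries equal to ``missing_token`` come back as NaN.  The companion of
    :func:`write_phylip`, and the input format for running the tree search
    standalone on an externally computed matrix.
    """
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        if len(parts) != n + 1:
            raise ValueError(f"row {parts[0]!r} has {len(parts) - 1} entries, expected {n}")
        rows.append(
            [np.nan if p == missing_token else float(p) for p in parts[1:]]
        )
    return labels, np.array(rows)


def write_phylip(avg: AverageMatrix, missing_token: str = "-1") -> str:
    """PHYLIP square distance matrix; missing entries as ``missing_token``."""
    D = avg.D
    lines = [f"{avg.n}"]
    for i, lab in enumerate(avg.labels):
        cells = []
        for j in range(avg.n):
            if i != j and avg.mask[i, j]:
                cells.append(missing_token)
            else:
                cells.append(f"{D[i, j]:.10g}")
        lines.append(f"{lab:<10s} " + " ".join(cells))
    return "\n".join(lines) + "\n"
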