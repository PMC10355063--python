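"""Synthetic data: species trees, coalescent gene trees, gene-tree error
with correlated support values, and missing-data models.

This module provides everything needed to exercise the whole pipeline
without external datasets:

* uniform random binary species trees with configurable branch lengths in
  coalescent units;
* multispecies-coalescent (MSC) gene trees — one lineage per species at
  the leaves, Kingman coalescence (each lineage pair merging at rate 1)
  within each species-tree branch for its duration, with the root branch
  treated as infinite;
* topological gene-tree error injected as random NNI moves, with branch
  supports drawn from separate laws for correctly and incorrectly
  estimated edges (mimicking how real support correlates with
  correctness);
* the two missing-data regimes used for incomplete-matrix experiments:
  i.i.d. deletion of a fixed-size random taxon subset per gene, and
  clade-based deletion where each gene retains only the taxa of one
  uniformly chosen species-tree clade above a size threshold.

Everything is driven by an explicit seed and is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .evaluation import bipartitions
from .tree_model import Node, Tree, TreeValidationError, from_adjacency, to_adjacency

__all__ = [
    "MSCConfig",
    "generate_condition",
    "random_species_tree",
    "species_tree_fixed_internal",
    "msc_simulate",
    "inject_error",
    "delete_iid",
    "delete_m_clade",
    "quartet_concordance_probability",
]

LengthLaw = Callable[[np.random.Generator], float]


@dataclass
class MSCConfig:
    """Bundle of generator settings for a full synthetic condition."""

    n_species: int = 16
    k_genes: int = 100
    seed: int = 0
    internal_length: float = 0.5  # coalescent units
    error_nni_count: int = 0
    deletion_model: str = "none"  # none | iid | m_clade
    deletion_m: int = 0
    deletion_x: float = 0.5

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if self.internal_length <= 0:
            raise ValueError("branch lengths must be positive")
        if self.deletion_model == "iid" and not (0 < self.deletion_m < self.n_species):
            raise ValueError("iid deletion needs 0 < m < n")
        if self.deletion_model == "m_clade" and not (0 < self.deletion_x <= 1):
            raise ValueError("m_clade needs 0 < x <= 1")


def generate_condition(config: MSCConfig) -> tuple[Tree, list[Tree]]:
    """Materialize a full synthetic condition from an :class:`MSCConfig`.

    Returns the model species tree and the k gene trees after the
    configured error injection and deletion model.
    """
    rng = np.random.default_rng(config.seed)
    species = species_tree_fixed_internal(
        config.n_species, config.internal_length, rng
    )
    genes = msc_simulate(species, config.k_genes, rng)
    if config.error_nni_count:
        genes = inject_error(genes, config.error_nni_count, rng)
    if config.deletion_model == "iid":
        genes = delete_iid(genes, config.deletion_m, rng)
    elif config.deletion_model == "m_clade":
        genes = delete_m_clade(genes, species, config.deletion_x, rng)
    return species, genes


def quartet_concordance_probability(t: float) -> float:
    """P(gene-tree quartet matches the species tree) for internal length t.

    Closed-form MSC result for a 4-taxon species tree whose single internal
    branch has length t coalescent units: 1 - (2/3) exp(-t).
    """
    return 1.0 - (2.0 / 3.0) * math.exp(-t)


def random_species_tree(
    n: int,
    seed: int | np.random.Generator = 0,
    length_law: Optional[LengthLaw] = None,
    labels: Optional[Sequence[str]] = None,
) -> Tree:
    """Uniform random rooted binary species tree on n labelled leaves.

    The unrooted topology is built by sequentially attaching each new leaf
    to a uniformly chosen edge, which makes all (2n-5)!! unrooted
    topologies equally likely; the root is then placed on a uniformly
    chosen edge.  Branch lengths (coalescent units) are drawn per edge from
    ``length_law`` (default: 0.1 + Exponential(mean 0.9), keeping branches
    away from zero the way simulated species trees do).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length_law is None:
        length_law = lambda r: 0.1 + r.exponential(0.9)
    if labels is None:
        labels = [f"t{i}" for i in range(n)]

    # grow the unrooted topology: leaves 0..n-1, internals from n
    adj: dict[int, list[int]] = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
    next_internal = n + 1
    for leaf in range(3, n):
        edges = sorted((min(u, v), max(u, v)) for u in adj for v in adj[u] if u < v)
        u, v = edges[rng.integers(len(edges))]
        adj[u][adj[u].index(v)] = next_internal
        adj[v][adj[v].index(u)] = next_internal
        adj[next_internal] = [u, v, leaf]
        adj[leaf] = [next_internal]
        next_internal += 1

    # root on a uniformly chosen edge
    edges = sorted((min(u, v), max(u, v)) for u in adj for v in adj[u] if u < v)
    ru, rv = edges[rng.integers(len(edges))]

    def build(v: int, parent: int) -> Node:
        node = Node(label=labels[v] if v < n else None)
        node.length = float(length_law(rng))
        for u in sorted(adj[v]):
            if u != parent:
                node.add_child(build(u, v))
        return node

    root = Node()
    root.add_child(build(ru, rv))
    root.add_child(build(rv, ru))
    return Tree(root)


def species_tree_fixed_internal(
    n: int,
    internal_length: float,
    seed: int | np.random.Generator = 0,
    leaf_length: float = 1.0,
) -> Tree:
    """Random topology with every internal branch set to one length.

    Under the MSC only internal branch durations shape discordance, so
    fixing them pins the ILS level of the condition while the topology
    varies with the seed.
    """
    t = random_species_tree(n, seed, length_law=lambda r: 1.0)
    for node in t.preorder():
        if node is t.root:
            continue
        node.length = leaf_length if node.is_leaf else internal_length
    return t


# --------------------------------------------------------------------------
# Multispecies coalescent
# --------------------------------------------------------------------------


def _coalesce_in_branch(
    lineages: list[tuple[Node, float]],
    duration: float,
    rng: np.random.Generator,
) -> list[tuple[Node, float]]:
    """Kingman coalescence among (gene node, pending length) lineages.

    With j lineages the waiting time to the next merger is Exponential with
    rate j(j-1)/2; the merging pair is uniform.  ``pending`` accumulates the
    coalescent time since each gene node was created and becomes the child
    branch length at the merger.
    """
    elapsed = 0.0
    lineages = list(lineages)
    while len(lineages) > 1:
        j = len(lineages)
        wait = rng.exponential(1.0) / (j * (j - 1) / 2.0)
        if elapsed + wait > duration:
            break
        elapsed += wait
        ia, ib = rng.choice(j, size=2, replace=False)
        ia, ib = sorted((int(ia), int(ib)))
        na, pa = lineages[ib]
        nb, pb = lineages[ia]
        parent = Node()
        # pending counts time since the child node's creation (negative for
        # nodes created within this branch), so pending + elapsed is the
        # child's branch length at the merger
        na.length = pa + elapsed
        nb.length = pb + elapsed
        parent.add_child(nb)
        parent.add_child(na)
        del lineages[ib]
        del lineages[ia]
        lineages.append((parent, -elapsed))
    # survivors age by the full duration
    return [(node, pending + duration) for node, pending in lineages]


def msc_simulate(
    species_tree: Tree,
    k: int,
    seed: int | np.random.Generator = 0,
) -> list[Tree]:
    """Simulate k gene trees under the MSC within the species tree.

    Branch lengths of the species tree are in coalescent units; leaves
    contribute one lineage each.  Returned gene trees carry coalescent-unit
    branch lengths and a (redundant, degree-2) root from the final merger;
    downstream code treats them as unrooted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes: list[Tree] = []
    for _ in range(k):
        def simulate(node: Node) -> list[tuple[Node, float]]:
            if node.is_leaf:
                incoming = [(Node(label=node.label), 0.0)]
            else:
                incoming = []
                for c in node.children:
                    incoming.extend(simulate(c))
            if node.parent is None:
                # root branch: effectively infinite duration
                out = _coalesce_in_branch(incoming, math.inf, rng)
                return out
            duration = node.length
            if duration is None:
                raise TreeValidationError("species tree branch without length")
            return _coalesce_in_branch(incoming, duration, rng)

        (root_node, _), = simulate(species_tree.root)
        genes.append(Tree(root_node))
    return genes


# --------------------------------------------------------------------------
# Gene-tree error and support annotation
# --------------------------------------------------------------------------


def _default_correct_law(rng: np.random.Generator) -> float:
    return 0.6 + 0.4 * rng.beta(5.0, 1.0)


def _default_wrong_law(rng: np.random.Generator) -> float:
    return 0.7 * rng.beta(2.0, 5.0)


def _random_nni_adj(
    adj: dict[int, list[int]],
    n_leaves: int,
    rng: np.random.Generator,
) -> None:
    """One uniform random NNI, in place, on an unrooted binary adjacency."""
    internal = [
        (u, v)
        for u in adj
        for v in adj[u]
        if u < v and len(adj[u]) > 1 and len(adj[v]) > 1
    ]
    if not internal:
        return
    u, v = internal[rng.integers(len(internal))]
    a = [x for x in adj[u] if x != v][rng.integers(2)]
    c = [x for x in adj[v] if x != u][rng.integers(2)]
    adj[u][adj[u].index(a)] = c
    adj[v][adj[v].index(c)] = a
    adj[a][adj[a].index(u)] = v
    adj[c][adj[c].index(v)] = u


def inject_error(
    gene_trees: Sequence[Tree],
    count: int,
    seed: int | np.random.Generator = 0,
    correct_law: LengthLaw = _default_correct_law,
    wrong_law: LengthLaw = _default_wrong_law,
    length_jitter_sd: float = 0.25,
) -> list[Tree]:
    """Perturb gene trees and annotate supports correlated with correctness.

    Each tree receives ``count`` uniform random NNI moves.  Every internal
    edge of the perturbed tree then gets a support draw: edges whose
    bipartition exists in the original (true) gene tree draw from
    ``correct_law`` (high supports), newly created edges from ``wrong_law``
    (low supports).  Branch lengths are multiplied by a lognormal jitter.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[Tree] = []
    for tree in gene_trees:
        true_splits = bipartitions(tree)
        adj, attrs, leaf_names = to_adjacency(tree)
        n_leaves = len(leaf_names)
        for _ in range(count):
            _random_nni_adj(adj, n_leaves, rng)
        # rebuild lengths: keep each surviving edge's length where its
        # endpoints still share an edge, else resample from the originals
        lengths = [a["length"] for a in attrs.values() if a["length"] is not None]
        mean_len = float(np.mean(lengths)) if lengths else 1.0
        new_attrs: dict[frozenset, dict] = {}
        for u in adj:
            for v in adj[u]:
                if u < v:
                    key = frozenset((u, v))
                    old = attrs.get(key, {})
                    base = old.get("length")
                    if base is None:
                        base = mean_len
                    jitter = float(rng.lognormal(0.0, length_jitter_sd))
                    new_attrs[key] = {"length": base * jitter, "support": None}
        perturbed = from_adjacency(adj, new_attrs, leaf_names)
        est_splits_by_node: list[tuple[Node, frozenset]] = []
        all_leaves = frozenset(perturbed.leaf_labels())
        ref = min(all_leaves)
        below: dict[int, frozenset] = {}
        for node in perturbed.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
                continue
            side = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = side
            if node.parent is None or len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            canon = side if ref not in side else all_leaves - side
            node.support = (
                float(correct_law(rng))
                if canon in true_splits
                else float(wrong_law(rng))
            )
        out.append(perturbed)
    return out


# --------------------------------------------------------------------------
# Missing-data models
# --------------------------------------------------------------------------


def delete_iid(
    gene_trees: Sequence[Tree],
    m: int,
    seed: int | np.random.Generator = 0,
) -> list[Tree]:
    """Delete a uniform random m-subset of taxa from each gene tree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for tree in gene_trees:
        labs = sorted(tree.leaf_labels())
        n = len(labs)
        if not 0 < m < n:
            raise ValueError(f"need 0 < m < n (m={m}, n={n})")
        if n - m < 4:
            raise ValueError(
                f"deleting {m} of {n} taxa leaves fewer than 4 leaves"
            )
        drop = rng.choice(n, size=m, replace=False)
        keep = set(labs) - {labs[int(i)] for i in drop}
        out.append(tree.restrict_to(keep))
    return out


def _rooted_clades(species_tree: Tree) -> list[frozenset]:
    clades = []
    below: dict[int, frozenset] = {}
    for node in species_tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
        else:
            s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            clades.append(s)
    return clades


def delete_m_clade(
    gene_trees: Sequence[Tree],
    species_tree: Tree,
    x: float,
    seed: int | np.random.Generator = 0,
) -> list[Tree]:
    """Clade-based deletion: each gene keeps one species-tree clade.

    Qualifying clades of the rooted species tree have at least ceil(x * n)
    taxa (the root clade always qualifies); each gene tree is pruned to the
    taxa of a uniformly chosen qualifying clade.
    """
    if not 0 < x <= 1:
        raise ValueError("need 0 < x <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = species_tree.n_leaves
    threshold = math.ceil(x * n)
    qualifying = sorted(
        (c for c in _rooted_clades(species_tree) if len(c) >= threshold),
        key=lambda c: tuple(sorted(c)),
    )
    if not qualifying:
        raise ValueError("no clade meets the size threshold")
    out = []
    for tree in gene_trees:
        clade = qualifying[rng.integers(len(qualifying))]
        keep = clade & set(tree.leaf_labels())
        out.append(tree.restrict_to(keep))
    return out
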