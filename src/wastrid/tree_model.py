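"""Tree containers and newick I/O for gene and species trees.

Trees are stored in a rooted representation (parent/child links) because it
makes traversal simple, but every downstream quantity is a function of the
*unrooted* topology: a degree-2 root is suppressed before edges are counted,
and no operation's result may depend on where the stored root sits.

Edges carry two optional annotations read from newick input:

* ``length`` — branch length, usually in substitution units, printed after
  a colon;
* ``support`` — a statistical confidence in the branch (bootstrap,
  SH-like, approximate-Bayes, ...), attached only to internal edges, read
  either from internal node labels (the FastTree/IQ-TREE convention) or
  from ``[&...]`` / ``[...]`` comments.

Both annotations belong to the edge above a node in the rooted storage.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "TaxonRegistry",
    "SupportScale",
    "TreeParseError",
    "TreeValidationError",
    "read_gene_trees",
    "parse_newick",
    "write_tree",
    "normalize_supports",
    "to_adjacency",
    "from_adjacency",
]


class TreeParseError(ValueError):
    """Raised when a newick source cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


class Node:
    """A node of a rooted tree representation.

    ``length`` and ``support`` describe the edge connecting this node to its
    parent; both are ``None`` when the annotation is absent (never 0).
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class Tree:
    """A phylogenetic tree with rooted storage and unrooted semantics."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # ---------------------------------------------------------------- walks
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    # ---------------------------------------------------------------- copies
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root))

    def unrooted_copy(self) -> "Tree":
        """Copy with any degree-2 root suppressed.

        The two root-incident edges describe a single unrooted edge; they
        are merged with lengths summed and support taken as the defined
        annotation (the mean if both halves are annotated — they label the
        same split, so they normally agree).
        """
        t = self.copy()
        root = t.root
        while len(root.children) == 2 and not all(c.is_leaf for c in root.children):
            a, b = root.children
            host = a if not a.is_leaf else b
            other = b if host is a else a
            # other becomes a child of host; merge the two root edges
            if host.length is None and other.length is None:
                other.length = None
            else:
                other.length = (host.length or 0.0) + (other.length or 0.0)
            if host.support is not None and other.support is not None:
                other.support = 0.5 * (host.support + other.support)
            elif other.support is None:
                other.support = host.support
            host.parent = None
            host.length = None
            host.support = None
            host.add_child(other)
            t.root = root = host
        return t

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dupes}")
        for node in self.preorder():
            if node.is_leaf and not node.label:
                raise TreeValidationError("leaf with empty label")
            if not node.is_leaf and node is not self.root and len(node.children) < 2:
                raise TreeValidationError("internal node with a single child")

    # ------------------------------------------------------------- reshaping
    def suppress_unifurcations(self) -> None:
        """Remove internal nodes with a single child, concatenating edges.

        Lengths add; the support kept is the defined one (mean if both are
        defined), matching the unrooted merge rule.
        """
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                (child,) = node.children
                if node.parent is None:
                    # root with one child: the child becomes the root
                    child.parent = None
                    child.length = None
                    child.support = None
                    self.root = child
                else:
                    parent = node.parent
                    if node.length is None and child.length is None:
                        merged_len = None
                    else:
                        merged_len = (node.length or 0.0) + (child.length or 0.0)
                    if node.support is not None and child.support is not None:
                        merged_sup = 0.5 * (node.support + child.support)
                    elif child.support is None:
                        merged_sup = node.support
                    else:
                        merged_sup = child.support
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    child.length = merged_len
                    child.support = merged_sup
                changed = True

    def restrict_to(self, labels: set[str] | Sequence[str]) -> "Tree":
        """Copy of the tree pruned to ``labels``.

        Degree-2 nodes created by pruning are suppressed with edge lengths
        summed, so weighted path lengths between retained leaves are
        preserved.
        """
        keep = set(labels)
        t = self.copy()

        def prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return node if node.label in keep else None
            kept = []
            for c in list(node.children):
                sub = prune(c)
                if sub is not None:
                    kept.append(sub)
            if not kept:
                return None
            node.children = []
            for c in kept:
                node.add_child(c)
            return node

        new_root = prune(t.root)
        if new_root is None:
            raise TreeValidationError("restriction removes every leaf")
        new_root.parent = None
        t.root = new_root
        t.suppress_unifurcations()
        return t


class TaxonRegistry:
    """Bijection between taxon labels and matrix indices.

    Index order is first-appearance order across the input, which fixes the
    row/column order of every matrix the pipeline produces.
    """

    def __init__(self, labels: Optional[Sequence[str]] = None) -> None:
        self._labels: list[str] = []
        self._index: dict[str, int] = {}
        if labels:
            for lab in labels:
                self.add(lab)

    def add(self, label: str) -> int:
        if not label:
            raise TreeValidationError("empty taxon label")
        if label not in self._index:
            self._index[label] = len(self._labels)
            self._labels.append(label)
        return self._index[label]

    def index(self, label: str) -> int:
        return self._index[label]

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)


# --------------------------------------------------------------------------
# Support scales
# --------------------------------------------------------------------------


class SupportScale(Enum):
    """Declared scale of raw branch-support annotations.

    Each scale maps affinely onto [0, 1]:

    * ``raw01`` — already a probability-like value in [0, 1];
    * ``percent100`` — bootstrap-style percentages in [0, 100];
    * ``abayes`` — approximate-Bayes supports, whose analytic minimum is
      1/3, mapped by (s - 1/3) / (2/3) so that 1/3 -> 0 and 1 -> 1;
    * ``none`` — input carries no supports.
    """

    RAW01 = "raw01"
    PERCENT100 = "percent100"
    ABAYES = "abayes"
    NONE = "none"

    def to_unit(self, value: float, tol: float = 1e-9) -> float:
        if self is SupportScale.RAW01:
            lo, hi = 0.0, 1.0
            mapped = value
        elif self is SupportScale.PERCENT100:
            lo, hi = 0.0, 100.0
            mapped = value / 100.0
        elif self is SupportScale.ABAYES:
            lo, hi = 1.0 / 3.0, 1.0
            mapped = (value - 1.0 / 3.0) / (2.0 / 3.0)
        else:
            raise ValueError("scale 'none' has no mapping")
        if value < lo - tol or value > hi + tol:
            raise TreeValidationError(
                f"support {value!r} outside declared {self.value} range [{lo}, {hi}]"
            )
        return min(1.0, max(0.0, mapped))


def normalize_supports(
    tree: Tree,
    scale: SupportScale | str = SupportScale.RAW01,
    missing_policy: float = 1.0,
) -> Tree:
    """Return a copy with every internal-edge support mapped into [0, 1].

    Leaf-incident edges are always fully trusted (weight 1 downstream), so
    any annotation on them is cleared.  Internal edges lacking a support are
    assigned ``missing_policy`` (default 1.0, which degrades gracefully to
    unweighted behaviour) with a warning.
    """
    if isinstance(scale, str):
        scale = SupportScale(scale)
    t = tree.copy()
    n_missing = 0
    for node in t.preorder():
        if node is t.root:
            node.support = None
            continue
        if node.is_leaf:
            node.support = None
            continue
        if node.support is None:
            node.support = missing_policy
            n_missing += 1
        elif scale is SupportScale.NONE:
            node.support = missing_policy
        else:
            try:
                node.support = scale.to_unit(node.support)
            except TreeValidationError as exc:
                below = sorted(
                    c.label for c in _subtree_leaves(node)
                )[:4]
                raise TreeValidationError(
                    f"{exc} (edge above clade containing {below})"
                ) from None
    if n_missing and scale is not SupportScale.NONE:
        warnings.warn(
            f"{n_missing} internal edge(s) lacked support; assigned "
            f"{missing_policy}",
            stacklevel=2,
        )
    return t


def _subtree_leaves(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v.is_leaf:
            out.append(v)
        else:
            stack.extend(v.children)
    return out


# --------------------------------------------------------------------------
# Newick I/O
# --------------------------------------------------------------------------

_FLOAT_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _support_from_comments(dnode: "dendropy.Node") -> Optional[float]:
    for ann in dnode.annotations:
        if ann.name.lower() in ("support", "posterior", "prob", "pp"):
            try:
                return float(ann.value)
            except (TypeError, ValueError):
                continue
    for comment in dnode.comments:
        m = _FLOAT_RE.search(comment)
        if m:
            return float(m.group(0))
    return None


def _from_dendropy(dtree: "dendropy.Tree", dialect: str) -> Tree:
    def convert(dnode: "dendropy.Node") -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(label=label, length=dnode.edge.length)
        if dnode.is_internal():
            if dialect == "node_label":
                if dnode.label is not None:
                    try:
                        node.support = float(dnode.label)
                    except ValueError:
                        node.support = None
            elif dialect == "comment":
                node.support = _support_from_comments(dnode)
            else:
                raise ValueError(f"unknown support dialect: {dialect!r}")
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    root.support = None
    return Tree(root)


def parse_newick(text: str, support_dialect: str = "node_label") -> Tree:
    """Parse one newick string into a :class:`Tree` and validate it."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=(support_dialect == "comment"),
        )
    except Exception as exc:
        raise TreeParseError(f"malformed newick: {exc}") from None
    tree = _from_dendropy(dtree, support_dialect)
    tree.validate()
    return tree


def read_gene_trees(
    source: str,
    support_dialect: str = "node_label",
) -> tuple[list[Tree], TaxonRegistry]:
    """Read a multi-tree newick source (path or literal text), one per line.

    Returns the trees in file order plus a :class:`TaxonRegistry` covering
    the union of their leaf labels, indexed by first appearance.
    """
    if "(" in source or ";" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    trees: list[Tree] = []
    registry = TaxonRegistry()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            tree = parse_newick(line, support_dialect)
        except (TreeParseError, TreeValidationError) as exc:
            raise TreeParseError(f"line {lineno}: {exc}") from None
        for lab in tree.leaf_labels():
            registry.add(lab)
        trees.append(tree)
    if not trees:
        raise TreeParseError("no trees found in input")
    return trees, registry


def _format_float(x: float) -> str:
    # >= 10 significant digits so lengths round-trip
    s = f"{x:.12g}"
    return s


def write_tree(tree: Tree) -> str:
    """Serialize a tree to newick, supports as internal node labels."""

    def render(node: Node) -> str:
        if node.is_leaf:
            out = node.label or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            out = f"({inner})"
            if node.support is not None and node.parent is not None:
                out += _format_float(node.support)
        if node.length is not None:
            out += f":{_format_float(node.length)}"
        return out

    return render(tree.root) + ";"


# --------------------------------------------------------------------------
# Adjacency conversion (used by rearrangement code and the search engine)
# --------------------------------------------------------------------------


def to_adjacency(
    tree: Tree,
) -> tuple[dict[int, list[int]], dict[frozenset, dict], dict[int, str]]:
    """Unrooted adjacency view of a tree.

    Returns ``(adj, edge_attrs, leaf_names)`` where nodes are small integers
    (leaves first, in leaf-iteration order), ``edge_attrs`` maps
    ``frozenset({u, v})`` to ``{"length": ..., "support": ...}`` and
    ``leaf_names`` maps leaf ids to labels.  The degree-2 root, if any, is
    suppressed first.
    """
    t = tree.unrooted_copy()
    leaves = t.leaves()
    ids: dict[int, int] = {}
    leaf_names: dict[int, str] = {}
    for i, leaf in enumerate(leaves):
        ids[id(leaf)] = i
        leaf_names[i] = leaf.label
    next_id = len(leaves)
    for node in t.preorder():
        if not node.is_leaf:
            ids[id(node)] = next_id
            next_id += 1
    adj: dict[int, list[int]] = {i: [] for i in range(next_id)}
    edge_attrs: dict[frozenset, dict] = {}
    for node in t.preorder():
        if node.parent is None:
            continue
        u, v = ids[id(node.parent)], ids[id(node)]
        adj[u].append(v)
        adj[v].append(u)
        edge_attrs[frozenset((u, v))] = {
            "length": node.length,
            "support": node.support,
        }
    return adj, edge_attrs, leaf_names


def from_adjacency(
    adj: dict[int, list[int]],
    edge_attrs: Optional[dict[frozenset, dict]] = None,
    leaf_names: Optional[dict[int, str]] = None,
) -> Tree:
    """Rebuild a rooted :class:`Tree` from an unrooted adjacency view.

    The tree is rooted at the internal node adjacent to the smallest leaf
    id, which makes the conversion deterministic.
    """
    n_leaves = sum(1 for v, nb in adj.items() if len(nb) == 1)
    if len(adj) == 2:
        a, b = sorted(adj)
        root = Node()
        for k, v in enumerate((a, b)):
            child = Node(label=leaf_names.get(v, str(v)) if leaf_names else str(v))
            if edge_attrs and k == 0:
                at = edge_attrs.get(frozenset((a, b)), {})
                child.length = at.get("length")
            root.add_child(child)
        return Tree(root)
    leaf0 = min(v for v, nb in adj.items() if len(nb) == 1)
    root_id = adj[leaf0][0]

    def build(v: int, parent: int) -> Node:
        nbrs = adj[v]
        if len(nbrs) == 1:
            node = Node(label=leaf_names.get(v, str(v)) if leaf_names else str(v))
        else:
            node = Node()
        if parent >= 0 and edge_attrs is not None:
            at = edge_attrs.get(frozenset((v, parent)), {})
            node.length = at.get("length")
            if len(nbrs) > 1:
                node.support = at.get("support")
        for u in sorted(nbrs):
            if u != parent:
                node.add_child(build(u, v))
        return node

    return Tree(build(root_id, -1))
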