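"""Per-gene distance tables vs graph-search oracles, and averaging."""

import numpy as np
import pytest

from wastrid.tree_model import TaxonRegistry, TreeValidationError, parse_newick
from wastrid.weighted_distance import (
    AverageMatrix,
    EdgeWeightMode,
    accumulate,
    average_matrix,
    gene_scale,
    per_gene_distances,
    write_phylip,
)

from conftest import oracle_path_sums, random_annotated_tree


def table_as_dict(tab, labels):
    out = {}
    m = len(tab.leaf_indices)
    for i in range(m):
        for j in range(i + 1, m):
            out[frozenset((labels[tab.leaf_indices[i]], labels[tab.leaf_indices[j]]))] = tab.table[i, j]
    return out


def weight_fn(mode, n_leaves, scale=1.0):
    def w(u, v, attrs, adj):
        leaf_incident = len(adj[u]) == 1 or len(adj[v]) == 1
        if mode == "unweighted":
            return 1.0
        if mode == "support":
            return 1.0 if leaf_incident else attrs["support"]
        return attrs["length"] / scale

    return w


def test_quartet_edge_counts():
    t = parse_newick("((a,b),(c,d));")
    reg = TaxonRegistry(["a", "b", "c", "d"])
    tab = per_gene_distances(t, EdgeWeightMode("unweighted"), reg)
    assert tab.table[0, 1] == 2  # a-b
    assert tab.table[0, 2] == 3  # a-c
    assert tab.table[2, 3] == 2  # c-d


def test_quartet_support_mode_single_internal_edge():
    """A rooted quartet has one unrooted internal edge; with s = 0.5 the
    cross distance is 1 + 0.5 + 1 and the cherry distance stays 2."""
    t = parse_newick("((a,b)0.5,(c,d)0.5);")
    reg = TaxonRegistry(["a", "b", "c", "d"])
    tab = per_gene_distances(t, EdgeWeightMode("support"), reg)
    assert tab.table[0, 2] == pytest.approx(2.5)
    assert tab.table[0, 1] == pytest.approx(2.0)


def test_gene_scale_quartet_and_star():
    t = parse_newick("((a:1,b:1):1,(c:1,d:1):0);")  # diameter a..c = 3
    assert gene_scale(t) == pytest.approx(3.0)
    star = parse_newick("(a:2,b:3,c:5);")
    assert gene_scale(star) == pytest.approx(8.0)


def test_gene_scale_matches_bruteforce(rng):
    for _ in range(10):
        t = random_annotated_tree(rng, 30, polytomy_prob=0.15)
        oracle = oracle_path_sums(t, lambda u, v, a, adj: a["length"])
        assert gene_scale(t) == pytest.approx(max(oracle.values()), rel=1e-12)


def test_zero_diameter_rejected():
    t = parse_newick("((a:0,b:0):0,(c:0,d:0):0);")
    with pytest.raises(TreeValidationError, match="diameter"):
        gene_scale(t)


@pytest.mark.parametrize(
    "mode",
    [
        EdgeWeightMode("unweighted"),
        EdgeWeightMode("support"),
        EdgeWeightMode("pathlength", "none"),
        EdgeWeightMode("pathlength", "max_path"),
    ],
    ids=["unweighted", "support", "pl-raw", "pl-norm"],
)
def test_per_gene_distances_match_dijkstra_oracle(rng, mode):
    """Post-order tables equal per-leaf Dijkstra sums on random trees
    with polytomies, in every weighting mode."""
    for trial in range(12):
        n = int(rng.integers(5, 25))
        t = random_annotated_tree(rng, n, polytomy_prob=0.2)
        labels = sorted(t.leaf_labels())
        reg = TaxonRegistry(labels)
        scale = 1.0
        if mode.mode == "pathlength" and mode.normalization == "max_path":
            scale = gene_scale(t)
        got = table_as_dict(per_gene_distances(t, mode, reg), labels)
        want = oracle_path_sums(t, weight_fn(mode.mode, n, scale))
        assert got.keys() == want.keys()
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-9), key


def test_unweighted_entries_are_integers_geq_two(rng):
    t = random_annotated_tree(rng, 12, polytomy_prob=0.3)
    reg = TaxonRegistry(sorted(t.leaf_labels()))
    tab = per_gene_distances(t, EdgeWeightMode("unweighted"), reg).table
    off = tab[~np.eye(12, dtype=bool)]
    assert np.all(off >= 2) and np.all(off == np.round(off))


def test_support_all_ones_equals_unweighted(rng):
    t = random_annotated_tree(rng, 15)
    for v in t.preorder():
        if not v.is_leaf and v.parent is not None:
            v.support = 1.0
    reg = TaxonRegistry(sorted(t.leaf_labels()))
    a = per_gene_distances(t, EdgeWeightMode("support"), reg).table
    b = per_gene_distances(t, EdgeWeightMode("unweighted"), reg).table
    assert np.array_equal(a, b)


def test_lowering_one_support_weakly_lowers_distances(rng):
    t = random_annotated_tree(rng, 12)
    reg = TaxonRegistry(sorted(t.leaf_labels()))
    before = per_gene_distances(t, EdgeWeightMode("support"), reg).table
    internals = [v for v in t.preorder() if not v.is_leaf and v.parent is not None]
    victim = internals[3]
    old = victim.support
    victim.support = old * 0.5
    after = per_gene_distances(t, EdgeWeightMode("support"), reg).table
    diff = before - after
    assert np.all(diff >= -1e-12)
    assert np.any(diff > 1e-9)
    changed = diff > 1e-12
    # unchanged entries are exactly equal
    assert np.array_equal(before[~changed], after[~changed])


def test_max_path_normalization_bounds_entries_at_one(rng):
    for _ in range(5):
        t = random_annotated_tree(rng, 14)
        reg = TaxonRegistry(sorted(t.leaf_labels()))
        tab = per_gene_distances(t, EdgeWeightMode("pathlength", "max_path"), reg).table
        assert tab.max() == pytest.approx(1.0, abs=1e-9)


def test_accumulate_mean_and_missing():
    reg = TaxonRegistry(["a", "b", "c"])
    t1 = parse_newick("((a,b),(c,x4));")
    t2 = parse_newick("((a,x5),(b,x6));")
    reg2 = TaxonRegistry(["a", "b", "c", "x4", "x5", "x6"])
    mode = EdgeWeightMode("unweighted")
    avg = accumulate(
        [per_gene_distances(t, mode, reg2, i) for i, t in enumerate((t1, t2))],
        reg2,
    )
    # a-b is a cherry (2 edges) in gene 1 and 3 edges apart in gene 2
    ia, ib, ic = reg2.index("a"), reg2.index("b"), reg2.index("c")
    assert avg.counts[ia, ib] == 2
    assert avg.D[ia, ib] == pytest.approx(2.5)
    # c never co-occurs with x5
    ix5 = reg2.index("x5")
    assert avg.counts[ic, ix5] == 0 and avg.mask[ic, ix5]
    assert np.isnan(avg.D[ic, ix5])


def test_accumulate_matches_naive_double_loop(rng):
    labels = [f"t{i}" for i in range(12)]
    reg = TaxonRegistry(labels)
    mode = EdgeWeightMode("unweighted")
    trees = []
    for _ in range(20):
        subset = sorted(
            rng.choice(12, size=int(rng.integers(4, 12)), replace=False)
        )
        trees.append(random_annotated_tree(rng, len(subset),
                                           labels=[labels[i] for i in subset]))
    tables = [per_gene_distances(t, mode, reg, i) for i, t in enumerate(trees)]
    avg = accumulate(tables, reg)
    # naive: loop over label pairs and genes
    for i in range(12):
        for j in range(i + 1, 12):
            vals = []
            for t, tab in zip(trees, tables):
                labs = set(t.leaf_labels())
                if labels[i] in labs and labels[j] in labs:
                    d = table_as_dict(tab, labels)[frozenset((labels[i], labels[j]))]
                    vals.append(d)
            if vals:
                assert avg.counts[i, j] == len(vals)
                assert avg.D[i, j] == pytest.approx(sum(vals) / len(vals))
            else:
                assert avg.mask[i, j]


def test_phylip_export_roundtrips_values(rng):
    from wastrid.weighted_distance import read_phylip

    t = random_annotated_tree(rng, 6)
    reg = TaxonRegistry(sorted(t.leaf_labels()))
    avg = average_matrix([t], EdgeWeightMode("unweighted"), reg)
    text = write_phylip(avg)
    lines = text.strip().splitlines()
    assert lines[0].strip() == "6"
    labels, M = read_phylip(text)
    assert labels == avg.labels
    np.testing.assert_allclose(M, avg.D, atol=1e-9)


def test_phylip_missing_entries_round_trip():
    from wastrid.weighted_distance import read_phylip

    counts = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    sums = np.array([[0, 2.0, 0], [2.0, 0, 4.0], [0, 4.0, 0]])
    avg = AverageMatrix(sums=sums, counts=counts, labels=list("abc"))
    labels, M = read_phylip(write_phylip(avg))
    assert np.isnan(M[0, 2]) and np.isnan(M[2, 0])
    assert M[0, 1] == 2.0 and M[1, 2] == 4.0
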