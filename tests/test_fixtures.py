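"""Generator statistics: topology uniformity, MSC calibration at reduced
sample sizes, error injection, and the two deletion models."""

import math
from collections import Counter

import numpy as np
import pytest

from wastrid.evaluation import bipartitions, nrf
from wastrid.fixtures import (
    delete_iid,
    delete_m_clade,
    inject_error,
    msc_simulate,
    quartet_concordance_probability,
    random_species_tree,
    species_tree_fixed_internal,
)
from wastrid.tree_model import parse_newick, write_tree


def test_species_tree_shape_and_determinism():
    t = random_species_tree(4, seed=1)
    assert len(bipartitions(t)) == 1  # binary quartet: one internal edge
    assert write_tree(random_species_tree(9, seed=7)) == write_tree(
        random_species_tree(9, seed=7)
    )
    assert write_tree(random_species_tree(9, seed=7)) != write_tree(
        random_species_tree(9, seed=8)
    )


def test_species_tree_topologies_uniform():
    """n=5 has 15 unrooted topologies; sequential uniform edge insertion
    must hit each with frequency 1/15 (checked at 3 sigma binomial)."""
    draws = 6000
    rng = np.random.default_rng(42)
    counts = Counter()
    for _ in range(draws):
        t = random_species_tree(5, rng)
        counts[frozenset(bipartitions(t))] += 1
    assert len(counts) == 15
    p = 1 / 15
    sigma = math.sqrt(draws * p * (1 - p))
    for topo, c in counts.items():
        assert abs(c - draws * p) < 3.5 * sigma


def test_no_ils_limit_reproduces_species_tree():
    sp = species_tree_fixed_internal(8, internal_length=20.0, seed=0)
    genes = msc_simulate(sp, 20, seed=1)
    assert all(nrf(sp, g) == 0.0 for g in genes)


@pytest.mark.parametrize("t", [0.0, 0.5])
def test_quartet_concordance_small_sample(t):
    """Pectinate quartet: concordance within 3 sigma of 1-(2/3)e^-t."""
    k = 2500
    sp = parse_newick(f"(((a:1,b:1):{t},c:1):1,d:1);")
    genes = msc_simulate(sp, k, seed=11)
    match = sum(1 for g in genes if nrf(sp, g) == 0.0)
    p = quartet_concordance_probability(t)
    sigma = math.sqrt(k * p * (1 - p))
    assert abs(match - k * p) < 3 * sigma


def test_msc_determinism():
    sp = species_tree_fixed_internal(6, 0.5, seed=0)
    g1 = [write_tree(t) for t in msc_simulate(sp, 5, seed=3)]
    g2 = [write_tree(t) for t in msc_simulate(sp, 5, seed=3)]
    assert g1 == g2


def test_inject_error_zero_moves_keeps_topology_high_support():
    sp = species_tree_fixed_internal(10, 0.5, seed=2)
    genes = msc_simulate(sp, 10, seed=3)
    noisy = inject_error(genes, count=0, seed=4)
    for g, e in zip(genes, noisy):
        assert nrf(g, e) == 0.0
        sups = [
            v.support
            for v in e.preorder()
            if not v.is_leaf and v.parent is not None
        ]
        assert all(s >= 0.6 for s in sups)  # all edges "correct"


def test_inject_error_monotone_in_count():
    sp = species_tree_fixed_internal(12, 0.5, seed=5)
    genes = msc_simulate(sp, 30, seed=6)
    means = []
    for count in (1, 3, 8):
        noisy = inject_error(genes, count, seed=7)
        means.append(np.mean([nrf(g, e) for g, e in zip(genes, noisy)]))
    assert means[0] < means[1] < means[2]


def test_inject_error_flags_match_bipartition_membership():
    """Supports separate by whether the edge's split exists in the true
    gene tree, checked exhaustively per tree."""
    sp = species_tree_fixed_internal(10, 0.5, seed=8)
    genes = msc_simulate(sp, 15, seed=9)
    noisy = inject_error(genes, count=2, seed=10)
    for g, e in zip(genes, noisy):
        true_splits = bipartitions(g)
        t = e.unrooted_copy()
        all_leaves = frozenset(t.leaf_labels())
        ref = min(all_leaves)
        below = {}
        for node in t.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
                continue
            side = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = side
            if node.parent is None or not (2 <= len(side) <= len(all_leaves) - 2):
                continue
            canon = side if ref not in side else all_leaves - side
            if canon in true_splits:
                assert node.support >= 0.6
            else:
                assert node.support < 0.7


def test_delete_iid_sizes_and_frequencies():
    sp = species_tree_fixed_internal(10, 0.5, seed=0)
    genes = msc_simulate(sp, 400, seed=1)
    out = delete_iid(genes, m=2, seed=2)
    assert all(t.n_leaves == 8 for t in out)
    # each taxon deleted with frequency m/n
    freq = Counter()
    taxa = set(sp.leaf_labels())
    for t in out:
        for missing in taxa - set(t.leaf_labels()):
            freq[missing] += 1
    p = 2 / 10
    sigma = math.sqrt(400 * p * (1 - p))
    for tax in taxa:
        assert abs(freq[tax] - 400 * p) < 3.5 * sigma


def test_delete_iid_too_aggressive_rejected():
    sp = species_tree_fixed_internal(6, 0.5, seed=0)
    genes = msc_simulate(sp, 2, seed=1)
    with pytest.raises(ValueError, match="fewer than 4"):
        delete_iid(genes, m=4, seed=2)


def test_delete_m_clade_outputs_are_clades():
    sp = species_tree_fixed_internal(12, 0.5, seed=3)
    genes = msc_simulate(sp, 60, seed=4)
    out = delete_m_clade(genes, sp, x=0.4, seed=5)
    clades = set()
    below = {}
    for node in sp.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
        else:
            s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            clades.add(s)
    for t in out:
        assert frozenset(t.leaf_labels()) in clades


def test_delete_m_clade_x1_keeps_everything():
    sp = species_tree_fixed_internal(8, 0.5, seed=6)
    genes = msc_simulate(sp, 10, seed=7)
    out = delete_m_clade(genes, sp, x=1.0, seed=8)
    assert all(t.n_leaves == 8 for t in out)


def test_generate_condition_applies_config():
    from wastrid.fixtures import MSCConfig, generate_condition

    cfg = MSCConfig(
        n_species=10, k_genes=12, seed=3, error_nni_count=2,
        deletion_model="iid", deletion_m=2,
    )
    sp, genes = generate_condition(cfg)
    assert sp.n_leaves == 10
    assert len(genes) == 12
    assert all(g.n_leaves == 8 for g in genes)
    sups = [
        v.support
        for g in genes
        for v in g.preorder()
        if not v.is_leaf and v.parent is not None
    ]
    assert sups and all(s is not None for s in sups)
    with pytest.raises(ValueError, match="m_clade"):
        MSCConfig(deletion_model="m_clade", deletion_x=0.0)


def test_delete_m_clade_fraction_decreasing_in_x():
    sp = species_tree_fixed_internal(16, 0.5, seed=9)
    genes = msc_simulate(sp, 120, seed=10)
    fractions = []
    for x in (0.2, 0.4, 0.6):
        out = delete_m_clade(genes, sp, x, seed=11)
        deleted = np.mean([1 - t.n_leaves / 16 for t in out])
        fractions.append(deleted)
    assert fractions[0] >= fractions[1] >= fractions[2]
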