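"""Neighbor joining, UPGMA, bipartitions and consensus."""
import numpy as np
import pytest

from conftest import tree_from_newick
from phyloboot.core import DataError, DistanceMatrix, Node, Tree
from phyloboot.simulate import random_tree
from phyloboot.trees import (bipartitions, consensus, count_bipartitions,
                             neighbor_joining, upgma)


def _reordered(m: DistanceMatrix, labels) -> np.ndarray:
    idx = [m.labels.index(l) for l in labels]
    return m.d[np.ix_(idx, idx)]


def test_nj_three_taxon_closed_form():
    d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    t = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
    lengths = {n.name: n.length for n in t.leaves()}
    assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


def test_nj_recovers_four_taxon_split_and_internal_length():
    # additive matrix from a tree with split AB|CD, internal branch 1
    labels = ("A", "B", "C", "D")
    d = np.array([[0, 3, 5, 6],
                  [3, 0, 6, 7],
                  [5, 6, 0, 7],
                  [6, 7, 7, 0]], dtype=float)
    t = neighbor_joining(DistanceMatrix(labels, d))
    assert bipartitions(t) == {frozenset({"C", "D"})}  # canonical for AB|CD
    internal = [n for n in t.postorder()
                if not n.is_leaf and n is not t.root]
    assert len(internal) == 1
    assert internal[0].length == pytest.approx(1.0)
    assert np.allclose(_reordered(t.path_length_matrix(), labels), d)


@pytest.mark.parametrize("n, seed", [(4, 0), (5, 1), (6, 2), (8, 3)])
def test_nj_inverts_additive_matrices(n, seed):
    true = random_tree(n, seed=seed)
    m = true.path_length_matrix()
    rebuilt = neighbor_joining(m)
    assert np.allclose(_reordered(rebuilt.path_length_matrix(), m.labels),
                       m.d, atol=1e-9)
    assert bipartitions(rebuilt) == bipartitions(true)


def test_nj_refuses_undefined_entries():
    d = np.array([[0, np.nan], [np.nan, 0]])
    m = DistanceMatrix(("A", "B"), d)
    with pytest.raises(DataError):
        neighbor_joining(m)
    with pytest.raises(DataError, match="at least 3"):
        neighbor_joining(DistanceMatrix(("A", "B"),
                                        np.array([[0, .1], [.1, 0]])))


def test_nj_negative_lengths_kept_unless_clamped():
    # matrix engineered to force a negative estimated branch
    d = np.array([[0.0, 0.561, 0.593, 0.339],
                  [0.561, 0.0, 0.593, 0.131],
                  [0.593, 0.593, 0.0, 0.26],
                  [0.339, 0.131, 0.26, 0.0]])
    m = DistanceMatrix(("A", "B", "C", "D"), d)
    kept = neighbor_joining(m)
    clamped = neighbor_joining(m, clamp_negative=True)
    assert min(n.length for n in kept.postorder()
               if n is not kept.root) < 0
    assert min(n.length for n in clamped.postorder()
               if n is not clamped.root) >= 0


def test_upgma_two_and_ultrametric_recovery():
    m2 = DistanceMatrix(("A", "B"), np.array([[0, 0.4], [0.4, 0]]))
    t2 = upgma(m2)
    assert t2.rooted
    assert all(n.length == pytest.approx(0.2) for n in t2.leaves())

    # ultrametric matrix: ((A:1,B:1):1,(C:1.5,D:1.5):0.5) root height 2
    d = np.array([[0, 2, 4, 4],
                  [2, 0, 4, 4],
                  [4, 4, 0, 3],
                  [4, 4, 3, 0]], dtype=float)
    t = upgma(DistanceMatrix(("A", "B", "C", "D"), d))
    pm = t.path_length_matrix()
    assert np.allclose(_reordered(pm, ("A", "B", "C", "D")), d, atol=1e-12)


def test_upgma_heights_monotone_on_random_input():
    rng = np.random.default_rng(9)
    n = 7
    d = rng.uniform(0.1, 2, (n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    t = upgma(DistanceMatrix(tuple(f"s{i}" for i in range(n)), d))
    # root-to-leaf distance identical for every leaf (ultrametric output)
    heights = {}
    def depth(node, acc):
        acc += node.length or 0
        if node.is_leaf:
            heights[node.name] = acc
        for c in node.children:
            depth(c, acc)
    depth(t.root, 0.0)
    vals = list(heights.values())
    assert np.allclose(vals, vals[0], atol=1e-12)


def test_bipartition_counts_and_invariance():
    t = tree_from_newick("((A,B),(C,D));")
    assert bipartitions(t) == {frozenset({"C", "D"})}
    star = tree_from_newick("(A,B,C,D);")
    assert bipartitions(star) == set()
    t10 = random_tree(10, seed=4)
    assert len(bipartitions(t10)) == 7  # n - 3


def test_consensus_of_identical_trees_is_that_tree():
    trees = [tree_from_newick("((A,B),(C,D),E);") for _ in range(4)]
    for mode in ("strict", "majority", "majority_extended"):
        cons = consensus(trees, mode)
        assert bipartitions(cons) == bipartitions(trees[0])
        sups = [n.support for n in cons.postorder()
                if not n.is_leaf and n is not cons.root]
        assert sups == [100.0, 100.0]


def test_majority_consensus_counts_and_support():
    trees = [tree_from_newick(s) for s in
             ["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"]]
    cons = consensus(trees, "majority")
    assert bipartitions(cons) == {frozenset({"C", "D"})}
    (sup,) = [n.support for n in cons.postorder()
              if not n.is_leaf and n is not cons.root]
    assert sup == pytest.approx(200 / 3, abs=1e-3)


def test_consensus_mode_nesting():
    # 6 trees on 5 taxa with a mixture of splits
    newicks = ["((A,B),(C,D),E);"] * 4 + ["((A,C),(B,D),E);",
                                          "((A,B),(C,E),D);"]
    trees = [tree_from_newick(s) for s in newicks]
    strict = bipartitions(consensus(trees, "strict"))
    majority = bipartitions(consensus(trees, "majority"))
    extended = bipartitions(consensus(trees, "majority_extended"))
    assert strict <= majority <= extended
    assert frozenset({"C", "D"}) in majority
    # extended picks up compatible minority splits
    assert len(extended) >= len(majority)


def test_majority_splits_pairwise_compatible():
    rng = np.random.default_rng(17)
    trees = [random_tree(6, seed=int(s)) for s in rng.integers(0, 50, 20)]
    freqs = count_bipartitions(trees)
    n = len(trees)
    from phyloboot.trees import _compatible
    taxa = frozenset(trees[0].leaf_names())
    maj = [f.split for f in freqs if f.count * 2 > n]
    for i, s in enumerate(maj):
        assert _compatible(s, maj[:i], taxa)


def test_consensus_rejects_mismatched_taxa():
    trees = [tree_from_newick("((A,B),(C,D));"),
             tree_from_newick("((A,B),(C,E));")]
    with pytest.raises(DataError):
        consensus(trees)


def test_consensus_against_dendropy_majority():
    """Independent cross-check of split percentages with dendropy."""
    import dendropy
    from phyloboot import phylip_io as pio
    trees = [random_tree(6, seed=s) for s in range(11)]
    cons = consensus(trees, "majority")
    ours = {tuple(sorted(s)): None for s in bipartitions(cons)}

    tl = dendropy.TreeList.get(data=pio.write_newick(trees),
                               schema="newick")
    dcons = tl.consensus(min_freq=0.5)
    dcons.encode_bipartitions()
    taxa = set(trees[0].leaf_names())
    ref = min(taxa)
    theirs = {}
    for edge in dcons.preorder_edge_iter():
        node = edge.head_node
        leafset = frozenset(lf.taxon.label
                            for lf in node.leaf_iter())
        if not 1 < len(leafset) < len(taxa) - 1:
            continue
        side = leafset if ref not in leafset else frozenset(taxa) - leafset
        if 1 < len(side) < len(taxa) - 1:
            theirs[tuple(sorted(side))] = None
    assert set(ours) == set(theirs)
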