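"""Step-matrix construction, Sankoff scoring, and parsimony search."""
import itertools

import numpy as np
import pytest

from conftest import all_unrooted_topologies, brute_force_sankoff, \
    tree_from_newick
from phyloboot.core import AMINO_ACIDS, DataError, ProteinAlignment
from phyloboot.parsimony import (STANDARD_CODE, build_step_matrix,
                                 sankoff_score, search_parsimony)
from phyloboot.simulate import random_tree, simulate_alignment


def test_step_matrix_basic_structure(step_matrix):
    c = step_matrix.cost
    assert c.shape == (20, 20)
    assert (np.diag(c) == 0).all()
    assert (c == c.T).all()
    assert (c >= 0).all() and c.max() <= 3  # standard code diameter
    # triangle inequality over amino-acid states
    for k in range(20):
        assert (c <= c[:, k:k + 1] + c[k:k + 1, :]).all()


def test_step_matrix_reference_costs(step_matrix):
    # single nonsynonymous step F->L (TTT->TTA); no 1-step F<->M codon pair
    assert step_matrix[("F", "L")] == 1
    assert step_matrix[("F", "M")] == 2
    assert step_matrix[("W", "M")] >= 1


def test_step_matrix_bfs_oracle(step_matrix):
    """Independent 0-1 BFS over the codon graph, then amino-acid state
    closure, reproduces every entry."""
    from collections import deque
    codons = sorted(STANDARD_CODE)
    idx = {c: i for i, c in enumerate(codons)}
    INF = 10 ** 6
    aa_cost = np.full((20, 20), INF, dtype=int)
    for src in codons:
        dist = {c: INF for c in codons}
        dist[src] = 0
        dq = deque([src])
        while dq:
            c = dq.popleft()
            for pos in range(3):
                for b in "TCAG":
                    if b == c[pos]:
                        continue
                    o = c[:pos] + b + c[pos + 1:]
                    if o not in dist:
                        continue
                    w = 0 if STANDARD_CODE[o] == STANDARD_CODE[c] else 1
                    if dist[c] + w < dist[o]:
                        dist[o] = dist[c] + w
                        (dq.appendleft if w == 0 else dq.append)(o)
        ia = AMINO_ACIDS.index(STANDARD_CODE[src])
        for tgt, dv in dist.items():
            ib = AMINO_ACIDS.index(STANDARD_CODE[tgt])
            aa_cost[ia, ib] = min(aa_cost[ia, ib], dv)
    aa_cost = np.minimum(aa_cost, aa_cost.T)
    for k in range(20):
        aa_cost = np.minimum(aa_cost, aa_cost[:, k:k + 1] + aa_cost[k:k + 1, :])
    assert (aa_cost == step_matrix.cost).all()


def test_step_matrix_rejects_incomplete_code():
    partial = {c: a for c, a in STANDARD_CODE.items() if a != "W"}
    with pytest.raises(DataError):
        build_step_matrix(partial)


def test_sankoff_constant_alignment_scores_zero(step_matrix):
    aln = ProteinAlignment(("a", "b", "c", "d"), ("AAA",) * 4)
    for t in all_unrooted_topologies(["a", "b", "c", "d"]):
        assert sankoff_score(t, aln, step_matrix) == 0


def test_sankoff_four_leaf_unit_example(step_matrix):
    aln = ProteinAlignment(("a", "b", "c", "d"), ("F", "F", "L", "L"))
    good = tree_from_newick("((a,b),(c,d));")
    bad = tree_from_newick("((a,c),(b,d));")
    assert sankoff_score(good, aln, step_matrix) == 1
    assert sankoff_score(bad, aln, step_matrix) == 2


@pytest.mark.parametrize("n, seed", [(4, 0), (5, 3), (6, 6)])
def test_sankoff_equals_brute_force(step_matrix, n, seed):
    tree = random_tree(n, seed=seed)
    aln = simulate_alignment(tree, 3, seed=seed + 50)
    assert sankoff_score(tree, aln, step_matrix) == \
        brute_force_sankoff(tree, aln, step_matrix.cost)


def test_sankoff_brute_force_with_missing_data(step_matrix):
    aln = ProteinAlignment(("a", "b", "c", "d"), ("F-", "FX", "L?", "LL"))
    for t in all_unrooted_topologies(["a", "b", "c", "d"]):
        assert sankoff_score(t, aln, step_matrix) == \
            brute_force_sankoff(t, aln, step_matrix.cost)


def test_sankoff_rerooting_and_leaf_order_invariance(step_matrix):
    tree = random_tree(6, seed=2)
    aln = simulate_alignment(tree, 20, seed=12)
    s0 = sankoff_score(tree, aln, step_matrix)
    for node in [n for n in tree.postorder()
                 if not n.is_leaf and n is not tree.root]:
        assert sankoff_score(tree.reroot_at(node), aln, step_matrix) == s0
    # permuting alignment rows changes nothing
    perm = np.random.default_rng(1).permutation(6)
    aln2 = ProteinAlignment(tuple(aln.names[i] for i in perm),
                            tuple(aln.seqs[i] for i in perm))
    assert sankoff_score(tree, aln2, step_matrix) == s0


def test_sankoff_site_additivity(step_matrix):
    tree = random_tree(5, seed=4)
    aln = simulate_alignment(tree, 10, seed=14)
    s0 = sankoff_score(tree, aln, step_matrix)
    # adding a constant site never changes the score
    plus_const = ProteinAlignment(aln.names,
                                  tuple(s + "A" for s in aln.seqs))
    assert sankoff_score(tree, plus_const, step_matrix) == s0
    # duplicating every site doubles the score
    doubled = ProteinAlignment(aln.names, tuple(s + s for s in aln.seqs))
    assert sankoff_score(tree, doubled, step_matrix) == 2 * s0


def test_search_three_taxa_unique_topology(step_matrix):
    aln = ProteinAlignment(("a", "b", "c"), ("FL", "LL", "FF"))
    res = search_parsimony(aln, step_matrix)
    assert len(res.trees) == 1
    # per-site one-node minimum
    expected = sum(min(sum(int(step_matrix.cost[AMINO_ACIDS.index(x),
                                                 k])
                           for x in col)
                       for k in range(20))
                   for col in aln.columns())
    assert res.score == expected


def test_search_recovers_homoplasy_free_topology(step_matrix):
    # single-step characters on a known 6-taxon tree: each informative
    # site supports one true split, so the generating tree is optimal
    names = ["a", "b", "c", "d", "e", "f"]
    true = tree_from_newick("(((a,b),c),((d,e),f));")
    seqs = {
        # split ab | rest and de | rest marked by F/L characters (cost 1)
        "a": "FAFA", "b": "FAFA", "c": "LAFA",
        "d": "LLLA", "e": "LLLA", "f": "LALA",
    }
    aln = ProteinAlignment(tuple(names), tuple(seqs[n] for n in names))
    res = search_parsimony(aln, step_matrix)
    from phyloboot.trees import bipartitions
    assert res.score == sankoff_score(true, aln, step_matrix)
    assert bipartitions(res.trees[0]) == bipartitions(true)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_search_matches_exhaustive_five_taxa(step_matrix, seed):
    rng = np.random.default_rng(seed)
    names = [f"t{i}" for i in range(5)]
    aln = ProteinAlignment(
        tuple(names),
        tuple("".join(rng.choice(list(AMINO_ACIDS), size=8))
              for _ in range(5)))
    best = min(sankoff_score(t, aln, step_matrix)
               for t in all_unrooted_topologies(names))
    res = search_parsimony(aln, step_matrix)
    assert res.score == best


def test_search_requires_three_taxa(step_matrix):
    with pytest.raises(DataError):
        search_parsimony(ProteinAlignment(("a", "b"), ("F", "L")),
                         step_matrix)
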