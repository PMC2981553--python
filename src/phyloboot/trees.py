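"""Distance tree construction and consensus with bootstrap support.

Neighbor joining (Saitou & Nei) is exact on additive matrices; UPGMA is
the ultrametric companion.  Consensus counts the non-trivial
bipartitions of the input trees and assembles the strict (100%),
majority-rule (>50%) or extended majority-rule tree, writing the
percentage occurrence of each retained split as its support value —
the consense convention.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import DataError, DistanceMatrix, Node, Tree


# ---------------------------------------------------------------------------
# neighbor joining / UPGMA
# ---------------------------------------------------------------------------

def neighbor_joining(m: DistanceMatrix, clamp_negative: bool = False) -> Tree:
    """Classic NJ; unrooted tree with a trifurcating top node.

    Ties in the Q criterion break to the lowest (i, j) index pair, so the
    result is deterministic.  Negative branch lengths are kept unless
    `clamp_negative`, mirroring PHYLIP's neighbor.
    """
    if m.has_undefined():
        raise DataError("distance matrix contains undefined (saturated) "
                        "entries; NJ refuses them")
    n = m.n
    if n < 3:
        raise DataError("NJ needs at least 3 taxa")
    nodes = [Node(name=label) for label in m.labels]
    d = m.d.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(active) > 3:
        r = len(active)
        dsub = d[np.ix_(active, active)]
        row_sums = dsub.sum(axis=1)
        Q = (r - 2) * dsub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minima: lexicographic scan of the argmin set
        # (Q[i,j] and Q[j,i] may differ by one ulp from summation order,
        # so tie pairs are canonicalised rather than filtered to i < j)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        ai, aj = min((min(int(a), int(b)), max(int(a), int(b)))
                     for a, b in ties)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        vj = dij - vi
        parent = Node()
        nodes[i].length = clamp(vi)
        nodes[j].length = clamp(vj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # grow the matrix with the new node's distances
        new_idx = d.shape[0]
        newrow = np.zeros(new_idx + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, :new_idx] = newrow[:new_idx]
        d[:new_idx, new_idx] = newrow[:new_idx]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    a = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    b = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    c = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node()
    for idx, ln in ((i, a), (j, b), (k, c)):
        nodes[idx].length = clamp(ln)
        root.add_child(nodes[idx])
    return Tree(root, rooted=False)


def upgma(m: DistanceMatrix) -> Tree:
    """Average-linkage clustering; rooted ultrametric tree.

    Node heights (half the merge distance) are non-decreasing; exact on
    ultrametric input.
    """
    if m.has_undefined():
        raise DataError("distance matrix contains undefined entries")
    n = m.n
    clusters: dict[int, tuple[Node, int, float]] = {
        i: (Node(name=m.labels[i]), 1, 0.0) for i in range(n)}
    d = {frozenset((i, j)): m.d[i, j] for i in range(n) for j in range(i)}
    next_id = n
    while len(clusters) > 1:
        # smallest pairwise distance; ties to lowest (i, j)
        best = min(d.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0]))))
        pair, dij = best
        i, j = sorted(pair)
        node_i, size_i, h_i = clusters.pop(i)
        node_j, size_j, h_j = clusters.pop(j)
        height = dij / 2.0
        parent = Node()
        node_i.length = height - h_i
        node_j.length = height - h_j
        parent.add_child(node_i)
        parent.add_child(node_j)
        for k in list(clusters):
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((next_id, k))] = (
                (dik * size_i + djk * size_j) / (size_i + size_j))
        del d[pair]
        clusters[next_id] = (parent, size_i + size_j, height)
        next_id += 1
    (root, _, _), = clusters.values()
    return Tree(root, rooted=True)


# ---------------------------------------------------------------------------
# bipartitions and consensus
# ---------------------------------------------------------------------------

def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the tree, one per internal edge.

    Each split is stored canonically as the side NOT containing the
    reference taxon (the lexicographically smallest leaf name), making
    the set invariant under re-rooting and rotation.
    """
    names = tree.leaf_names()
    full = frozenset(names)
    ref = min(names)
    splits: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.name,))
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node is tree.root:
            continue
        side = clade if ref not in clade else full - clade
        if 1 < len(side) < len(full) - 1:
            splits.add(side)
    # a rooted tree's root edge pair induces one split counted once: the
    # two root children give complementary clades, already deduplicated
    return splits


def _compatible(split: frozenset[str], accepted: Iterable[frozenset[str]],
                full: frozenset[str]) -> bool:
    for other in accepted:
        if not (split <= other or other <= split
                or split.isdisjoint(other)
                or split | other == full):
            return False
    return True


@dataclass(frozen=True)
class SplitFrequency:
    split: frozenset[str]
    count: int
    percent: float


def count_bipartitions(trees: Sequence[Tree]) -> list[SplitFrequency]:
    """Occurrence counts of every non-trivial split over the input trees,
    sorted by descending count, ties by canonical split order."""
    if not trees:
        raise DataError("no input trees")
    taxa = frozenset(trees[0].leaf_names())
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        if frozenset(t.leaf_names()) != taxa:
            raise DataError("input trees disagree on the taxon set")
        for s in bipartitions(t):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    items = sorted(counts.items(),
                   key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
    return [SplitFrequency(s, c, 100.0 * c / n) for s, c in items]


def consensus(trees: Sequence[Tree], mode: str = "majority") -> Tree:
    """Consensus tree with percentage support on each internal edge.

    strict: splits present in every tree.  majority: splits in strictly
    more than half.  majority_extended: majority splits plus remaining
    splits, in descending frequency (ties by canonical order), each added
    only if compatible with everything already accepted.
    """
    if mode not in ("strict", "majority", "majority_extended"):
        raise DataError(f"unknown consensus mode {mode!r}")
    freqs = count_bipartitions(trees)
    n = len(trees)
    taxa = frozenset(trees[0].leaf_names())
    accepted: list[SplitFrequency] = []
    for f in freqs:
        if mode == "strict":
            if f.count == n:
                accepted.append(f)
        elif mode == "majority":
            if f.count * 2 > n:
                accepted.append(f)
        else:
            if f.count * 2 > n or _compatible(
                    f.split, (a.split for a in accepted), taxa):
                accepted.append(f)
    return _tree_from_splits(accepted, taxa)


def _tree_from_splits(splits: Sequence[SplitFrequency],
                      taxa: frozenset[str]) -> Tree:
    """Assemble the (possibly multifurcating) tree of a compatible,
    canonically oriented split set."""
    ref = min(taxa)
    # canonical sides exclude ref, so the sides form a laminar family:
    # build the rooted tree of their containment order, ref at the top
    ordered = sorted(splits, key=lambda f: (-len(f.split),
                                            tuple(sorted(f.split))))
    root = Node()
    clade_of: list[tuple[frozenset[str], Node]] = [(taxa - {ref}, root)]
    # note: top "clade" is everything but ref; ref hangs off the root
    nodes: list[tuple[frozenset[str], Node]] = []
    for f in ordered:
        parent = root
        parent_clade = taxa - {ref}
        for clade, node in nodes:
            if f.split <= clade and len(clade) < len(parent_clade):
                parent, parent_clade = node, clade
        child = Node(support=round(f.percent, 4))
        parent.add_child(child)
        nodes.append((f.split, child))
    for leaf_name in sorted(taxa):
        if leaf_name == ref:
            parent = root
        else:
            parent = root
            parent_clade = taxa - {ref}
            for clade, node in nodes:
                if leaf_name in clade and len(clade) < len(parent_clade):
                    parent, parent_clade = node, clade
        parent.add_child(Node(name=leaf_name))
    return Tree(root, rooted=False)
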