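"""Genetic-code-constrained protein parsimony (protpars-equivalent).

The cost of replacing one amino acid by another is the minimum number of
amino-acid-changing single-nucleotide steps on any codon path between
them through the sense codons of the genetic code — synonymous moves are
free, stop codons are excluded as intermediates.  Trees are scored by
Sankoff's dynamic programme over that step matrix and searched by
stepwise addition followed by nearest-neighbor-interchange hill
climbing.

Gap, '?' and the ambiguity codes are treated as fully missing (zero cost
to every state); protpars's 21st "deletion" state is deliberately not
modelled, keeping the step matrix purely code-derived.
"""
from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (AMINO_ACIDS, DataError, MISSING_RESIDUES, Node,
                   ProteinAlignment, Tree)

#: the standard genetic code, sense codons only
STANDARD_CODE: dict[str, str] = {}
_BASES = "TCAG"
_CODE_STR = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    if _CODE_STR[_i] != "*":
        STANDARD_CODE[_b1 + _b2 + _b3] = _CODE_STR[_i]

_INF = 10 ** 6  # larger than any attainable score; stays integer-exact


@dataclass(frozen=True)
class StepMatrix:
    """Minimum amino-acid replacements between every residue pair."""

    cost: np.ndarray   #: (20, 20) int matrix, symmetric, zero diagonal
    code: str = "standard"

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return int(self.cost[AMINO_ACIDS.index(pair[0]),
                              AMINO_ACIDS.index(pair[1])])


def build_step_matrix(code: Optional[dict[str, str]] = None) -> StepMatrix:
    """Shortest-path costs over the sense-codon graph.

    Edges join codons one nucleotide apart; weight 0 for synonymous
    moves, 1 for amino-acid-changing moves.  cost(a, b) minimises over
    all codon choices for a and b (0-1 BFS via Dijkstra).
    """
    table = STANDARD_CODE if code is None else dict(code)
    codons = sorted(table)
    if not codons:
        raise DataError("empty genetic-code table")
    aas = set(table.values())
    missing = set(AMINO_ACIDS) - aas
    if missing:
        raise DataError(f"code table encodes no codon for {sorted(missing)}")
    neighbors: dict[str, list[str]] = {c: [] for c in codons}
    for c in codons:
        for pos in range(3):
            for b in _BASES:
                if b != c[pos]:
                    other = c[:pos] + b + c[pos + 1:]
                    if other in table:
                        neighbors[c].append(other)
    # Dijkstra from each codon with 0/1 weights
    dist_codon: dict[str, dict[str, int]] = {}
    for src in codons:
        dist = {c: _INF for c in codons}
        dist[src] = 0
        pq = [(0, src)]
        while pq:
            dcur, c = heapq.heappop(pq)
            if dcur > dist[c]:
                continue
            for nb in neighbors[c]:
                w = 0 if table[nb] == table[c] else 1
                nd = dcur + w
                if nd < dist[nb]:
                    dist[nb] = nd
                    heapq.heappush(pq, (nd, nb))
        dist_codon[src] = dist
    n = len(AMINO_ACIDS)
    cost = np.full((n, n), _INF, dtype=np.int64)
    for ca in codons:
        ia = AMINO_ACIDS.index(table[ca])
        for cb in codons:
            ib = AMINO_ACIDS.index(table[cb])
            v = dist_codon[ca][cb]
            if v < cost[ia, ib]:
                cost[ia, ib] = v
    cost = np.minimum(cost, cost.T)
    # metric closure over amino-acid states: a parsimony reconstruction may
    # place any residue at an internal node, so a replacement can be realised
    # through an intermediate amino acid even where no single codon path
    # does (serine's two synonymously disconnected codon families make the
    # raw path costs violate the triangle inequality at N<->W)
    for k in range(n):
        cost = np.minimum(cost, cost[:, k:k + 1] + cost[k:k + 1, :])
    return StepMatrix(cost=cost, code="standard" if code is None else "custom")


# ---------------------------------------------------------------------------
# Sankoff scoring
# ---------------------------------------------------------------------------

def _leaf_cost_vectors(aln: ProteinAlignment) -> dict[str, np.ndarray]:
    """(L, 20) cost arrays per taxon: 0 at the observed state (or all
    zeros for missing residues), a large constant elsewhere."""
    out = {}
    for name, seq in zip(aln.names, aln.seqs):
        C = np.full((len(seq), 20), _INF, dtype=np.int64)
        for s, ch in enumerate(seq):
            if ch in MISSING_RESIDUES:
                C[s, :] = 0
            else:
                C[s, AMINO_ACIDS.index(ch)] = 0
        out[name] = C
    return out


def _sankoff_from_vectors(tree: Tree, leaf_costs: dict[str, np.ndarray],
                          cost: np.ndarray) -> int:
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            try:
                below[id(node)] = leaf_costs[node.name]
            except KeyError:
                raise DataError(f"tree leaf {node.name!r} not in alignment")
            continue
        acc = None
        for ch in node.children:
            C = below.pop(id(ch))
            # min over child state j of cost[i, j] + C[:, j], capped so
            # missing-data INF entries do not overflow
            contrib = np.min(np.minimum(C, _INF)[:, None, :]
                             + cost[None, :, :], axis=2)
            acc = contrib if acc is None else acc + contrib
        below[id(node)] = acc
    root_cost = below[id(tree.root)]
    per_site = root_cost.min(axis=1)
    return int(per_site.sum())


def sankoff_score(tree: Tree, aln: ProteinAlignment,
                  steps: Optional[StepMatrix] = None) -> int:
    """Minimum total replacement cost of the alignment on the tree.

    Rooting-invariant (the step matrix is symmetric); leaves must match
    the alignment's taxa exactly.
    """
    if steps is None:
        steps = build_step_matrix()
    if set(tree.leaf_names()) != set(aln.names):
        raise DataError("tree leaves and alignment taxa differ")
    return _sankoff_from_vectors(tree, _leaf_cost_vectors(aln), steps.cost)


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsimonyResult:
    score: int
    trees: tuple[Tree, ...]


def _edges(tree: Tree) -> list[Node]:
    """Child endpoints of every edge, in deterministic preorder."""
    return [n for n in tree.preorder() if n is not tree.root]


def _attach(tree: Tree, edge_child: Node, leaf_name: str) -> Tree:
    """New tree with `leaf_name` attached in the middle of the edge above
    `edge_child` (topology only; no branch lengths)."""
    t = tree.copy()
    # locate the copied counterpart by preorder position
    orig = _edges(tree)
    cop = _edges(t)
    target = cop[orig.index(edge_child)]
    parent = target.parent
    mid = Node()
    idx = parent.children.index(target)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(target)
    mid.add_child(Node(name=leaf_name))
    return t


def _nni_neighbors(tree: Tree) -> list[Tree]:
    """All trees one NNI away, in deterministic edge/swap order.

    For each internal edge (u = parent, v = child, both internal), the
    two rearrangements swap one child of v with one non-v neighbor of u.
    """
    out = []
    edges = [n for n in _edges(tree) if not n.is_leaf]
    for k, v in enumerate(edges):
        u = v.parent
        # u's other neighbors: its other children, plus (if u is not the
        # root) its parent side, which we avoid by rerooting logic —
        # operating on the rooted representation, swapping with u's other
        # children covers both NNIs when u has >= 2 other children or a
        # parent; use the first other child as the swap partner
        others = [c for c in u.children if c is not v]
        if u is not tree.root and u.parent is not None:
            pass  # parent side handled implicitly by other-edge iteration
        if not others:
            continue
        a = others[0]
        for ci in range(len(v.children)):
            t = tree.copy()
            e_orig = _edges(tree)
            e_cop = _edges(t)
            v2 = e_cop[e_orig.index(v)]
            a2 = e_cop[e_orig.index(a)]
            u2 = v2.parent
            b2 = v2.children[ci]
            # swap a2 and b2
            ia = u2.children.index(a2)
            ib = v2.children.index(b2)
            u2.children[ia], v2.children[ib] = b2, a2
            a2.parent, b2.parent = v2, u2
            out.append(t)
    return out


def search_parsimony(replicate: ProteinAlignment,
                     steps: Optional[StepMatrix] = None,
                     addition_order: Optional[Sequence[str]] = None,
                     n_best: int = 1,
                     rearrange: str = "nni") -> ParsimonyResult:
    """Heuristic most-parsimonious tree(s) for one replicate.

    Stepwise addition in the given order (default: input order), each new
    taxon tried on every edge and kept at the best placement (ties break
    to the lowest edge index), then NNI hill climbing to a local optimum.
    """
    if steps is None:
        steps = build_step_matrix()
    if rearrange not in ("none", "nni"):
        raise DataError(f"unknown rearrangement {rearrange!r}")
    names = list(addition_order) if addition_order else list(replicate.names)
    if set(names) != set(replicate.names):
        raise DataError("addition order must be a permutation of the taxa")
    if len(names) < 3:
        raise DataError("parsimony search needs at least 3 taxa")
    leaf_costs = _leaf_cost_vectors(replicate)

    def score(t: Tree) -> int:
        return _sankoff_from_vectors(t, leaf_costs, steps.cost)

    root = Node()
    for nm in names[:3]:
        root.add_child(Node(name=nm))
    tree = Tree(root, rooted=False)
    for nm in names[3:]:
        best: Optional[tuple[int, int, Tree]] = None
        for ei, edge_child in enumerate(_edges(tree)):
            cand = _attach(tree, edge_child, nm)
            s = score(cand)
            if best is None or s < best[0]:
                best = (s, ei, cand)
        tree = best[2]
    from .trees import bipartitions  # local import avoids cycle at module load
    best_score = score(tree)
    best_trees = [tree]
    seen = [bipartitions(tree)]
    if rearrange == "nni" and len(names) > 3:
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(best_trees[0]):
                s = score(cand)
                if s < best_score:
                    best_score, best_trees = s, [cand]
                    seen = [bipartitions(cand)]
                    improved = True
                    break
                if s == best_score and len(best_trees) < n_best:
                    bp = bipartitions(cand)
                    if bp not in seen:
                        best_trees.append(cand)
                        seen.append(bp)
    return ParsimonyResult(score=best_score,
                           trees=tuple(best_trees[:max(1, n_best)]))
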