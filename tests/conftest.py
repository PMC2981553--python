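"""Shared fixtures and independent oracle helpers.

The oracles here (exhaustive topology enumeration, brute-force internal
state assignment) are deliberately naive re-derivations used to check
the dynamic-programming and search code against ground truth at small n.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from phyloboot.core import Node, ProteinAlignment, Tree
from phyloboot import phylip_io

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")


def tree_from_newick(s: str) -> Tree:
    return phylip_io.parse_newick(s)[0]


def all_unrooted_topologies(names: list[str]) -> list[Tree]:
    """Every unrooted binary topology on the given taxa, by exhaustive
    sequential addition (3, 15, 105, ... trees)."""

    def edges(t: Tree) -> list[Node]:
        return [n for n in t.preorder() if n is not t.root]

    root = Node()
    for nm in names[:3]:
        root.add_child(Node(name=nm))
    stack = [Tree(root)]
    for nm in names[3:]:
        grown = []
        for t in stack:
            for i in range(len(edges(t))):
                t2 = t.copy()
                target = edges(t2)[i]
                parent = target.parent
                mid = Node()
                k = parent.children.index(target)
                parent.children[k] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(Node(name=nm))
                grown.append(t2)
        stack = grown
    return stack


def brute_force_sankoff(tree: Tree, aln: ProteinAlignment,
                        cost: np.ndarray) -> int:
    """Minimum cost by enumerating every assignment of the 20 states to
    every internal node.  Exponential; n_taxa <= 6 only."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    seq_of = dict(zip(aln.names, aln.seqs))
    total = 0
    from phyloboot.core import AMINO_ACIDS, MISSING_RESIDUES
    for site in range(aln.length):
        best = None
        for assign in itertools.product(range(20), repeat=len(internals)):
            state = {id(n): a for n, a in zip(internals, assign)}
            s = 0
            for n in nodes:
                if n is tree.root:
                    continue
                if n.is_leaf:
                    ch = seq_of[n.name][site]
                    if ch in MISSING_RESIDUES:
                        continue  # free to match: zero cost to any state
                    a = AMINO_ACIDS.index(ch)
                else:
                    a = state[id(n)]
                s += cost[a, state[id(n.parent)]]
            if best is None or s < best:
                best = s
        total += best
    return int(total)


def brute_force_lnl(tree: Tree, aln: ProteinAlignment, model) -> float:
    """Log-likelihood by summing over every internal-node state
    combination; n_taxa <= 5 only."""
    from phyloboot.core import AMINO_ACIDS, MISSING_RESIDUES
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    seq_of = dict(zip(aln.names, aln.seqs))
    P = {id(n): model.transition_matrix(max(n.length or 1e-8, 1e-8))
         for n in nodes if n is not tree.root}
    lnl = 0.0
    for site in range(aln.length):
        like = 0.0
        for assign in itertools.product(range(20), repeat=len(internals)):
            state = {id(n): a for n, a in zip(internals, assign)}
            term = model.pi[state[id(tree.root)]]
            ok = True
            for n in nodes:
                if n is tree.root:
                    continue
                if n.is_leaf:
                    ch = seq_of[n.name][site]
                    if ch in MISSING_RESIDUES:
                        # missing leaf: sum over its states = row sum = 1
                        continue
                    a = AMINO_ACIDS.index(ch)
                else:
                    a = state[id(n)]
                term *= P[id(n)][state[id(n.parent)], a]
            like += term
        lnl += np.log(like)
    return float(lnl)


@pytest.fixture
def toy_alignment() -> ProteinAlignment:
    return ProteinAlignment(("seqA", "seqB", "seqC", "seqD"),
                            ("ACDEFGHIKLMNPQRSTVWY",
                             "ACDEFGHIKLMNPQRSTVWF",
                             "ACDEYGHIKLMNPQRSTVWF",
                             "GCDEYGHIKLMNPQRSTVWF"))


@pytest.fixture(scope="session")
def jtt():
    from phyloboot.models import get_model
    return get_model("JTT")


@pytest.fixture(scope="session")
def step_matrix():
    from phyloboot.parsimony import build_step_matrix
    return build_step_matrix()
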