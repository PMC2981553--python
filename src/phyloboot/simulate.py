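"""Sequence evolution along a phylogeny under an empirical model.

The fixture generator for the whole toolkit: draws root residues from
the model's stationary frequencies and propagates them down every branch
with the model's transition probabilities, yielding alignments whose
statistical properties (stationary composition, expected divergence per
branch length) match the generating model exactly.  Also provides a
seeded random-topology generator.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import AMINO_ACIDS, DataError, Node, ProteinAlignment, Tree
from .models import RateModel, get_model


def random_tree(n_taxa: int, seed: int = 0,
                names: Optional[Sequence[str]] = None,
                branch_length_range: tuple[float, float] = (0.02, 0.25),
                rooted: bool = False) -> Tree:
    """Random binary topology by sequential attachment on random edges,
    branch lengths uniform on `branch_length_range`.

    The default length range keeps typical pairwise divergence in the
    regime of a conserved single-gene protein family, where all
    corrected distances remain estimable.
    """
    if n_taxa < 3:
        raise DataError("need at least 3 taxa")
    if names is None:
        names = [f"t{i + 1}" for i in range(n_taxa)]
    if len(names) != n_taxa:
        raise DataError("names count does not match n_taxa")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    def bl() -> float:
        lo, hi = branch_length_range
        return float(rng.uniform(lo, hi))

    root = Node()
    for nm in names[:3]:
        root.add_child(Node(name=nm, length=bl()))
    tree = Tree(root, rooted=False)
    for nm in names[3:]:
        edges = [n for n in tree.preorder() if n is not tree.root]
        target = edges[int(rng.integers(0, len(edges)))]
        parent = target.parent
        mid = Node(length=bl())
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        half = (target.length or 0.0) / 2.0
        target.length = half
        mid.length = half if mid.length is None else bl()
        mid.add_child(target)
        mid.add_child(Node(name=nm, length=bl()))
    return tree


def simulate_alignment(tree: Tree, length: int,
                       model: Optional[RateModel] = None,
                       seed: int = 0) -> ProteinAlignment:
    """Evolve `length` independent sites down the tree; deterministic per
    seed.  Branch lengths are expected replacements per site; a total
    length of zero reproduces the root draw at every leaf."""
    if model is None:
        model = get_model("JTT")
    if length < 1:
        raise DataError("need at least one site")
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise DataError("tree needs at least two leaves")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(20, size=length, p=model.pi)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length or 0.0
        parent_states = states[id(node.parent)]
        if t <= 0:
            states[id(node)] = parent_states.copy()
            continue
        P = model.transition_matrix(t)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(length)
        rows = cum[parent_states]
        states[id(node)] = (u[:, None] > rows).sum(axis=1)
    seqs = tuple("".join(AMINO_ACIDS[s] for s in states[id(leaf)])
                 for leaf in leaves)
    names = tuple(leaf.name for leaf in leaves)
    return ProteinAlignment(names, seqs)
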