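"""Core domain types shared by every engine in the toolkit.

The unit of work is a protein multiple alignment; a bootstrap run is an
ordered stream of such alignments; distance engines produce symmetric
matrices; every tree engine produces (and consensus consumes) unrooted or
rooted phylogenies with optional branch lengths and per-edge support.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

#: canonical residue alphabet: 20 amino acids, ambiguity codes, gap, missing
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AMBIGUOUS = "BZX"
GAP_CHARS = "-?"
VALID_RESIDUES = frozenset(AMINO_ACIDS + AMBIGUOUS + GAP_CHARS)

#: residues excluded from pairwise comparison and treated as fully missing
#: in parsimony and likelihood calculations
MISSING_RESIDUES = frozenset(AMBIGUOUS + GAP_CHARS)


class DataError(ValueError):
    """Malformed or inconsistent phylogenetic input data."""


@dataclass(frozen=True)
class ProteinAlignment:
    """Named, equal-length amino-acid sequences.

    Sequences are uppercase strings over the 20 one-letter amino-acid
    codes plus B, Z, X (ambiguity), '-' (gap) and '?' (missing).
    """

    names: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise DataError("names and sequences differ in count")
        if len(self.names) < 2:
            raise DataError("alignment needs at least 2 sequences")
        if len(set(self.names)) != len(self.names):
            raise DataError("duplicate taxon names")
        length = len(self.seqs[0])
        if length < 1:
            raise DataError("alignment needs at least 1 site")
        for name, seq in zip(self.names, self.seqs):
            if len(seq) != length:
                raise DataError(
                    f"sequence {name!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - VALID_RESIDUES
            if bad:
                raise DataError(
                    f"illegal residue(s) {sorted(bad)} in sequence {name!r}"
                )

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "ProteinAlignment":
        names, seqs = zip(*pairs)
        return cls(tuple(names), tuple(s.upper() for s in seqs))

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def columns(self) -> Iterator[str]:
        for j in range(self.length):
            yield "".join(seq[j] for seq in self.seqs)

    def take_columns(self, idx: Sequence[int]) -> "ProteinAlignment":
        """New alignment keeping the given site columns in the given order."""
        seqs = tuple("".join(s[j] for j in idx) for s in self.seqs)
        return ProteinAlignment(self.names, seqs)

    def to_array(self) -> np.ndarray:
        """Integer-coded (n_taxa, length) array; missing/gap/ambiguous = -1."""
        code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        out = np.full((self.n_taxa, self.length), -1, dtype=np.int8)
        for i, seq in enumerate(self.seqs):
            for j, ch in enumerate(seq):
                out[i, j] = code.get(ch, -1)
        return out


@dataclass(frozen=True)
class ReplicateStream:
    """An ordered sequence of alignments sharing one taxon set and length.

    Bootstrap resampling preserves the site count, so every replicate in a
    stream has the same shape; jackknife streams share the reduced length.
    """

    replicates: tuple[ProteinAlignment, ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise DataError("empty replicate stream")
        first = self.replicates[0]
        for i, rep in enumerate(self.replicates):
            if rep.names != first.names:
                raise DataError(f"replicate {i} has a different taxon set")
            if rep.length != first.length:
                raise DataError(f"replicate {i} has length {rep.length}, "
                                f"expected {first.length}")

    @property
    def count(self) -> int:
        return len(self.replicates)

    def __iter__(self) -> Iterator[ProteinAlignment]:
        return iter(self.replicates)

    def __getitem__(self, i: int) -> ProteinAlignment:
        return self.replicates[i]


#: sentinel for a pairwise distance that could not be estimated (saturation)
UNDEFINED_DISTANCE = float("nan")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise evolutionary distances (substitutions/site).

    Undefined entries (saturated pairs) are stored as NaN; tree builders
    refuse matrices that contain them.
    """

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise DataError("distance matrix needs at least 2 taxa")
        if len(set(self.labels)) != n:
            raise DataError("duplicate taxon labels")
        d = np.asarray(self.d, dtype=float)
        if d.shape != (n, n):
            raise DataError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.allclose(np.diag(d), 0.0):
            raise DataError("diagonal must be zero")
        mask = ~np.isnan(d)
        if not np.allclose(np.where(mask, d, 0.0),
                           np.where(mask.T, d.T, 0.0), atol=1e-6):
            raise DataError("matrix not symmetric within 1e-6")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.labels)

    def has_undefined(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool(np.isnan(self.d[off]).any())


class Node:
    """A node of a phylogeny; the tree is a recursive structure of these."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None,
                 length: Optional[float] = None,
                 support: Optional[float] = None) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for ch in self.children:
            yield from ch.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for ch in self.children:
            yield from ch.preorder()


class Tree:
    """Rooted or unrooted phylogeny with optional lengths and supports.

    Unrooted trees are stored with a trifurcating (or higher-degree) top
    node; rooted trees have a bifurcating root.  Leaf names are unique.
    """

    def __init__(self, root: Node, rooted: bool = False) -> None:
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise DataError("duplicate leaf names in tree")

    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.name, node.length, node.support)
            for ch in node.children:
                c.add_child(clone(ch))
            return c
        return Tree(clone(self.root), rooted=self.rooted)

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder()
                   if n is not self.root)

    def path_length_matrix(self) -> "DistanceMatrix":
        """Leaf-to-leaf path lengths; exact additivity check companion."""
        leaves = self.leaves()
        labels = tuple(n.name for n in leaves)
        index = {id(n): i for i, n in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))
        # distances from each node down to the leaves below it, accumulated
        # upward; pairs are joined at their lowest common ancestor
        below: dict[int, list[tuple[int, float]]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = [(index[id(node)], 0.0)]
                continue
            groups = []
            for ch in node.children:
                grp = [(i, dist + (ch.length or 0.0))
                       for i, dist in below.pop(id(ch))]
                groups.append(grp)
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i, di in groups[a]:
                        for j, dj in groups[b]:
                            d[i, j] = d[j, i] = di + dj
            below[id(node)] = [p for grp in groups for p in grp]
        return DistanceMatrix(labels, d)

    def reroot_at(self, node: Node) -> "Tree":
        """Return a copy re-rooted so that `node`'s clone is the top node.

        Branch lengths are preserved; the operation is its own inverse up
        to the placement of the old root (degree-2 old roots are spliced
        out, keeping the unrooted topology identical).
        """
        mapping: dict[int, Node] = {}

        def clone_down(orig: Node, skip: Optional[Node]) -> Node:
            c = Node(orig.name, orig.length, orig.support)
            mapping[id(orig)] = c
            for ch in orig.children:
                if ch is skip:
                    continue
                c.add_child(clone_down(ch, None))
            return c

        new_root = Node(node.name, None, node.support)
        for ch in node.children:
            new_root.add_child(clone_down(ch, None))
        # walk up from node to the old root, reversing parent edges
        attach = new_root
        cur = node
        while cur.parent is not None:
            par = cur.parent
            up = Node(par.name, cur.length, par.support)
            for sib in par.children:
                if sib is cur:
                    continue
                up.add_child(clone_down(sib, None))
            cur = par
            attach.add_child(up)
            attach = up
        tree = Tree(new_root, rooted=False)
        _splice_degree_two(tree.root)
        return tree


def _splice_degree_two(root: Node) -> None:
    """Remove unnamed internal nodes with exactly one child (old roots)."""
    for node in list(root.postorder()):
        if node is root or node.is_leaf:
            continue
        if len(node.children) == 1:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
    # a top node with a single internal child carries no topological or
    # path-length information: promote the child (no leaf sits above it)
    while len(root.children) == 1 and not root.name and root.children[0].children:
        only = root.children[0]
        root.children = only.children
        for ch in root.children:
            ch.parent = root
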