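"""Readers and writers for the text formats the workflow touches.

PHYLIP alignments (interleaved and sequential, single dataset or a
seqboot-style concatenation of many), PHYLIP square / lower-triangular
distance matrices, and multi-tree Newick files.

Two name dialects are supported: strict PHYLIP (the taxon name is the
first 10 columns of the line, space-padded) and relaxed (whitespace
delimited).  Reading auto-detects; writing defaults to strict, the form
PHYLIP's own programs consume.
"""
from __future__ import annotations

import io
import re
from typing import Iterable, Optional, TextIO, Union

import dendropy
import numpy as np

from .core import (DataError, DistanceMatrix, Node, ProteinAlignment,
                   ReplicateStream, Tree, VALID_RESIDUES, _splice_degree_two)

_HEADER_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s*$")


def _as_stream(text: Union[str, TextIO]) -> TextIO:
    return io.StringIO(text) if isinstance(text, str) else text


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _clean_seq(chunk: str) -> str:
    """Strip whitespace and sequence-position digits PHYLIP allows in rows."""
    return "".join(c for c in chunk if not c.isspace() and not c.isdigit()).upper()


def _split_name(line: str, strict: bool) -> tuple[str, str]:
    if strict:
        name = line[:10].strip()
        rest = line[10:]
    else:
        parts = line.split(None, 1)
        name = parts[0]
        rest = parts[1] if len(parts) > 1 else ""
    if not name:
        raise DataError(f"missing taxon name in line {line!r}")
    return name, _clean_seq(rest)


class _LineReader:
    """Line source with pushback, so a failed dialect attempt can be
    replayed without losing the stream position of later datasets."""

    def __init__(self, stream: TextIO) -> None:
        self._stream = stream
        self._back: list[str] = []

    def readline(self) -> str:
        if self._back:
            return self._back.pop()
        return self._stream.readline()

    def push(self, lines: list[str]) -> None:
        self._back.extend(reversed(lines))


def read_alignment(text: Union[str, TextIO], layout: str = "auto",
                   dialect: str = "auto") -> ProteinAlignment:
    """Read one PHYLIP alignment (header line: taxon count, site count)."""
    reader = _LineReader(_as_stream(text))
    aln, _ = _read_one_alignment(reader, layout, dialect)
    return aln


def _read_one_alignment(reader: _LineReader, layout: str, dialect: str,
                        header: Optional[str] = None
                        ) -> tuple[ProteinAlignment, bool]:
    """Read one dataset.  With dialect='auto' the relaxed form is tried
    first and strict is the fallback: whichever yields a valid alignment
    wins, which resolves the inherent ambiguity of the two name fields."""
    if header is None:
        header = reader.readline()
        while header and not header.strip():
            header = reader.readline()
    if not header:
        raise DataError("empty input: no PHYLIP header line")
    m = _HEADER_RE.match(header)
    if not m:
        raise DataError(f"malformed PHYLIP header {header!r}")
    n, length = int(m.group(1)), int(m.group(2))
    if n < 2 or length < 1:
        raise DataError(f"implausible header: {n} taxa, {length} sites")

    attempts = {"auto": (False, True), "relaxed": (False,),
                "strict": (True,)}[dialect]
    last_error: Optional[DataError] = None
    for k, strict in enumerate(attempts):
        consumed: list[str] = []

        def next_line() -> str:
            line = reader.readline()
            if line:
                consumed.append(line)
            return line

        try:
            aln = _read_body(next_line, n, length, layout, strict)
            return aln, strict
        except DataError as exc:
            reader.push(consumed)
            if last_error is None:
                last_error = exc
    raise last_error


def _read_body(next_line, n: int, length: int, layout: str,
               strict: bool) -> ProteinAlignment:
    # first block: one line per taxon, name-led
    first_block = []
    while len(first_block) < n:
        line = next_line()
        if not line:
            raise DataError(f"truncated alignment: expected {n} taxon lines")
        if line.strip():
            first_block.append(line.rstrip("\n"))
    names, seqs = [], []
    for line in first_block:
        name, seq = _split_name(line, strict)
        names.append(name)
        seqs.append(seq)
    if len(set(names)) != len(names):
        raise DataError("duplicate taxon names")

    sequential = layout == "sequential"
    if layout == "auto":
        # sequential if the first block already carries full-length rows
        sequential = all(len(s) >= length for s in seqs)

    if sequential:
        # sequences may continue over following lines until full length
        for i in range(n):
            while len(seqs[i]) < length:
                line = next_line()
                if not line:
                    raise DataError(f"sequence {names[i]!r} shorter than "
                                    f"header length {length}")
                if not line.strip():
                    continue
                seqs[i] += _clean_seq(line)
                if i + 1 < n and len(seqs[i]) > length:
                    raise DataError(f"sequence {names[i]!r} overruns header "
                                    f"length {length}")
    else:
        # interleaved: repeated blocks of n bare-sequence lines
        while any(len(s) < length for s in seqs):
            block = []
            while len(block) < n:
                line = next_line()
                if not line:
                    raise DataError("truncated interleaved block")
                if line.strip():
                    block.append(line)
            for i, line in enumerate(block):
                seqs[i] += _clean_seq(line)

    for name, seq in zip(names, seqs):
        if len(seq) != length:
            raise DataError(f"sequence {name!r} has {len(seq)} residues, "
                            f"header says {length}")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise DataError(f"illegal residue(s) {sorted(bad)} in {name!r}")
    return ProteinAlignment(tuple(names), tuple(seqs))


def read_replicates(text: Union[str, TextIO], layout: str = "auto",
                    dialect: str = "auto") -> ReplicateStream:
    """Read a seqboot-style concatenation of one or more PHYLIP datasets.

    A new dataset begins wherever a header line ("int int") is legal,
    i.e. after the previous dataset is complete.
    """
    reader = _LineReader(_as_stream(text))
    reps = []
    while True:
        line = reader.readline()
        while line and not line.strip():
            line = reader.readline()
        if not line:
            break
        if not _HEADER_RE.match(line):
            raise DataError(f"trailing garbage after dataset {len(reps)}: "
                            f"{line!r}")
        aln, _ = _read_one_alignment(reader, layout, dialect, header=line)
        reps.append(aln)
    if not reps:
        raise DataError("no datasets found")
    return ReplicateStream(tuple(reps))


def write_alignment(aln: ProteinAlignment, layout: str = "sequential",
                    dialect: str = "strict", block_width: int = 60) -> str:
    """Serialise an alignment; inverse of :func:`read_alignment`."""
    if dialect == "strict":
        truncated = [name[:10] for name in aln.names]
        if len(set(truncated)) != len(truncated):
            raise DataError("taxon names collide after 10-character "
                            "truncation in strict dialect")
        name_field = [f"{t:<10}" for t in truncated]
    else:
        width = max(len(n) for n in aln.names) + 2
        name_field = [f"{n:<{width}}" for n in aln.names]
    out = [f"{aln.n_taxa} {aln.length}"]
    if layout == "sequential":
        for field, seq in zip(name_field, aln.seqs):
            out.append(field + seq)
    elif layout == "interleaved":
        first = True
        for start in range(0, aln.length, block_width):
            if not first:
                out.append("")
            for field, seq in zip(name_field, aln.seqs):
                chunk = seq[start:start + block_width]
                out.append((field if first else "") + chunk)
            first = False
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return "\n".join(out) + "\n"


def write_replicates(stream: ReplicateStream, layout: str = "sequential",
                     dialect: str = "strict") -> str:
    """Concatenate replicates in seqboot's multi-dataset convention."""
    return "".join(write_alignment(r, layout, dialect) for r in stream)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def read_distance_matrix(text: Union[str, TextIO]) -> DistanceMatrix:
    """Read a PHYLIP square or lower-triangular distance matrix."""
    stream = _as_stream(text)
    header = stream.readline()
    while header and not header.strip():
        header = stream.readline()
    try:
        n = int(header.split()[0])
    except (IndexError, ValueError):
        raise DataError(f"malformed distance-matrix header {header!r}")
    # rows may wrap over lines: a line whose first token is not numeric
    # starts a new taxon row, numeric-only lines continue the current one
    tokens_per_row: list[tuple[str, list[float]]] = []
    for raw in stream.read().splitlines():
        parts = raw.split()
        if not parts:
            continue
        try:
            float(parts[0])
            is_continuation = True
        except ValueError:
            is_continuation = False
        if is_continuation:
            if not tokens_per_row:
                raise DataError(f"matrix values before first taxon row: {raw!r}")
            tokens_per_row[-1][1].extend(float(x) for x in parts)
        else:
            tokens_per_row.append((parts[0], [float(x) for x in parts[1:]]))
    if len(tokens_per_row) != n:
        raise DataError(f"expected {n} matrix rows, found {len(tokens_per_row)}")
    labels = tuple(name for name, _ in tokens_per_row)
    counts = [len(v) for _, v in tokens_per_row]
    d = np.zeros((n, n))
    if counts == [n] * n:  # square
        for i, (_, vals) in enumerate(tokens_per_row):
            d[i] = vals
        finite = ~np.isnan(d)
        if (finite != finite.T).any() or not np.allclose(
                np.where(finite, d, 0.0), np.where(finite.T, d.T, 0.0),
                atol=1e-6):
            raise DataError("square matrix asymmetric beyond 1e-6")
        d = np.where(finite, (d + np.where(finite.T, d.T, d)) / 2.0, np.nan)
        np.fill_diagonal(d, 0.0)
    elif counts == list(range(n)):  # lower triangular
        for i, (_, vals) in enumerate(tokens_per_row):
            for j, v in enumerate(vals):
                d[i, j] = d[j, i] = v
    else:
        raise DataError(f"rows have {counts} values: neither square nor "
                        "lower-triangular")
    return DistanceMatrix(labels, d)


def read_distance_matrices(text: Union[str, TextIO]) -> list[DistanceMatrix]:
    """Read a concatenation of distance matrices (one per replicate).

    A line consisting of a single integer starts a new matrix block.
    """
    data = text if isinstance(text, str) else text.read()
    blocks: list[list[str]] = []
    for line in data.splitlines():
        parts = line.split()
        if len(parts) == 1:
            try:
                int(parts[0])
                blocks.append([line])
                continue
            except ValueError:
                pass
        if not parts:
            continue
        if not blocks:
            raise DataError(f"matrix rows before any header: {line!r}")
        blocks[-1].append(line)
    if not blocks:
        raise DataError("no distance matrices found")
    return [read_distance_matrix("\n".join(b) + "\n") for b in blocks]


def write_distance_matrix(m: DistanceMatrix, shape: str = "square") -> str:
    """Serialise a distance matrix; PHYLIP header + 10-column names."""
    out = [f"{m.n:5d}"]
    for i, label in enumerate(m.labels):
        upto = m.n if shape == "square" else i
        vals = "".join(f"{m.d[i, j]:10.6f}" for j in range(upto))
        out.append(f"{label[:10]:<10}{vals}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def _from_dendropy(dnode: dendropy.Node) -> Node:
    if dnode.taxon is not None:
        name = dnode.taxon.label
    else:
        name = None
    support: Optional[float] = None
    label = dnode.label
    if name is None and label is not None:
        try:
            support = float(label)
        except ValueError:
            name = label
    node = Node(name=name, length=dnode.edge.length, support=support)
    for ch in dnode.child_nodes():
        node.add_child(_from_dendropy(ch))
    return node


def parse_newick(text: Union[str, TextIO]) -> list[Tree]:
    """Parse a (multi-tree) Newick file.

    Numeric internal-node labels are read as support values, the
    convention PHYLIP's consense uses when writing consensus trees.
    """
    data = text if isinstance(text, str) else text.read()
    if not data.strip():
        raise DataError("empty Newick input")
    try:
        tlist = dendropy.TreeList.get(data=data, schema="newick",
                                      suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise DataError(f"Newick parse failure: {exc}") from exc
    trees = []
    for dtree in tlist:
        root = _from_dendropy(dtree.seed_node)
        rooted = len(root.children) == 2
        trees.append(Tree(root, rooted=rooted))
    return trees


def _newick_node(node: Node, with_support: bool) -> str:
    if node.is_leaf:
        s = node.name or ""
    else:
        s = "(" + ",".join(_newick_node(c, with_support)
                           for c in node.children) + ")"
        if with_support and node.support is not None:
            sup = node.support
            s += f"{sup:g}"
        elif node.name:
            s += node.name
    if node.length is not None:
        s += f":{node.length:.6g}"
    return s


def write_newick(trees: Union[Tree, Iterable[Tree]],
                 with_support: bool = True) -> str:
    """Serialise one or more trees, one per line, semicolon-terminated."""
    if isinstance(trees, Tree):
        trees = [trees]
    return "".join(_newick_node(t.root, with_support) + ";\n" for t in trees)
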