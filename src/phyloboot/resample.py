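"""Replicate generation (seqboot-equivalent) and replicate-count planning.

Bootstrap support values are themselves estimates: with n replicates the
observed bootstrap proportion p carries binomial sampling error
sqrt(p(1-p)/n).  ``plan_replicates`` inverts the normal approximation of
that error to tell a user how many replicates are needed for a target
confidence-interval half-width — e.g. 400 replicates for ±5% at 95%
confidence anywhere in the 50–100% support range, 2,500 for ±2%, and
3,500 for ±1% at a 90% support value.

Replicate i is a pure function of (seed, i): generating a stream in
chunks on many workers reproduces the serial stream exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.stats import norm

from .core import DataError, ProteinAlignment, ReplicateStream


def _replicate_rng(seed: int, i: int) -> np.random.Generator:
    """Counter-derived substream: independent of chunking across workers."""
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=seed, spawn_key=(i,))))


def bootstrap_stream(aln: ProteinAlignment, n: int,
                     seed: int = 0) -> ReplicateStream:
    """n bootstrap replicates: L site columns drawn with replacement."""
    if n < 1:
        raise DataError("need at least one replicate")
    L = aln.length
    reps = []
    for i in range(n):
        rng = _replicate_rng(seed, i)
        idx = rng.integers(0, L, size=L)
        reps.append(aln.take_columns(idx.tolist()))
    return ReplicateStream(tuple(reps))


def jackknife_stream(aln: ProteinAlignment, n: int,
                     seed: int = 0) -> ReplicateStream:
    """Delete-half jackknife: each replicate keeps ceil(L/2) distinct
    columns, in their original order."""
    if n < 1:
        raise DataError("need at least one replicate")
    L = aln.length
    keep = math.ceil(L / 2)
    reps = []
    for i in range(n):
        rng = _replicate_rng(seed, i)
        idx = np.sort(rng.choice(L, size=keep, replace=False))
        reps.append(aln.take_columns(idx.tolist()))
    return ReplicateStream(tuple(reps))


def permute_stream(aln: ProteinAlignment, n: int,
                   seed: int = 0) -> ReplicateStream:
    """Permute residues independently within each column across taxa."""
    if n < 1:
        raise DataError("need at least one replicate")
    cols = list(aln.columns())
    reps = []
    for i in range(n):
        rng = _replicate_rng(seed, i)
        permuted = []
        for col in cols:
            chars = list(col)
            rng.shuffle(chars)
            permuted.append(chars)
        seqs = tuple("".join(p[t] for p in permuted)
                     for t in range(aln.n_taxa))
        reps.append(ProteinAlignment(aln.names, seqs))
    return ReplicateStream(tuple(reps))


@dataclass(frozen=True)
class ReplicatePlan:
    """How many bootstrap replicates a target support precision needs."""

    epsilon: float      #: target CI half-width, as a proportion
    confidence: float   #: CI coverage level
    p: Union[float, str]  #: support value at which variance is evaluated
    n_raw: int          #: minimal replicate count from the formula
    n_rounded: int      #: n_raw rounded up to the next multiple of 100


def plan_replicates(epsilon: float, confidence: float = 0.95,
                    p: Union[float, str] = "worst") -> ReplicatePlan:
    """Minimal replicate count for a ±epsilon support CI at `confidence`.

    n = z^2 p(1-p) / epsilon^2 with z the two-sided normal quantile;
    p="worst" maximises the binomial variance over the 50–100% support
    range (p = 1/2, variance 1/4).  The result is also rounded up to the
    next multiple of 100, the granularity at which replicate counts are
    conventionally quoted.
    """
    if not 0 < epsilon < 0.5:
        raise DataError(f"epsilon must be in (0, 0.5), got {epsilon}")
    if not 0.5 < confidence < 1:
        raise DataError(f"confidence must be in (0.5, 1), got {confidence}")
    if p == "worst":
        v = 0.25
    else:
        if not 0.5 <= p <= 1:
            raise DataError(f"p must be in [0.5, 1] or 'worst', got {p}")
        v = p * (1 - p)
    z = norm.ppf((1 + confidence) / 2)
    n_raw = math.ceil(z * z * v / (epsilon * epsilon))
    n_raw = max(n_raw, 1)
    n_rounded = math.ceil(n_raw / 100) * 100
    return ReplicatePlan(epsilon, confidence, p, n_raw, n_rounded)
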