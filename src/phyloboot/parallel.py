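"""Chunked parallel execution of per-replicate analyses, plus the
parallel-scaling benchmark metrics.

The scheme: split a replicate stream into contiguous per-worker chunks
(one chunk per rank, sizes differing by at most one), run the same
analysis with the same options on every chunk, and merge the per-chunk
outputs back in rank order — so the merged result is identical, byte for
byte, to a serial run whatever the worker count.

Scaling of a parallel run is summarised against a baseline processor
count b (default 4):

    efficiency(n)          = 100 * b * t(b) / (n * t(n))   [percent]
    effective_speedup(n)   =       b * t(b) / t(n)         [processors]

i.e. how many processors' worth of perfect scaling the n-processor run
actually delivered.
"""
from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, TypeVar, Union

from .core import DataError, ReplicateStream

T = TypeVar("T")


@dataclass(frozen=True)
class ChunkPlan:
    """Contiguous per-worker slices of [0, n_replicates)."""

    n_replicates: int
    n_workers: int
    chunks: tuple[tuple[int, int], ...]  #: (start_index, length) per rank


def partition_replicates(n_replicates: int, n_workers: int) -> ChunkPlan:
    """Balanced contiguous chunks: the first n mod w workers get one
    extra replicate; empty chunks are legal when workers exceed work."""
    if n_replicates < 1:
        raise DataError("need at least one replicate")
    if n_workers < 1:
        raise DataError("need at least one worker")
    base, extra = divmod(n_replicates, n_workers)
    chunks = []
    start = 0
    for rank in range(n_workers):
        size = base + (1 if rank < extra else 0)
        chunks.append((start, size))
        start += size
    return ChunkPlan(n_replicates, n_workers, tuple(chunks))


class ReplicateError(RuntimeError):
    """An analysis failed on one replicate; carries its index."""

    def __init__(self, index: int, cause: BaseException) -> None:
        super().__init__(f"analysis failed on replicate {index}: {cause!r}")
        self.index = index
        self.cause = cause


def _run_chunk(args) -> list:
    analysis, reps, start = args
    out = []
    for offset, rep in enumerate(reps):
        try:
            out.append(analysis(rep))
        except Exception as exc:
            raise ReplicateError(start + offset, exc) from exc
    return out


def run_replicated(stream: ReplicateStream,
                   analysis: Callable[..., T],
                   n_workers: int = 1,
                   backend: str = "auto") -> list[T]:
    """Apply `analysis` to every replicate; results in replicate order.

    The analysis must be a pure function of one replicate (options bound
    beforehand, e.g. with functools.partial).  Output is identical to
    the n_workers=1 run for any worker count.  backend: "serial",
    "process", or "auto" (process pool whenever n_workers > 1; the
    analysis must then be picklable).
    """
    plan = partition_replicates(stream.count, n_workers)
    jobs = [(analysis, stream.replicates[s:s + sz], s)
            for s, sz in plan.chunks if sz > 0]
    if backend == "serial" or (backend == "auto" and n_workers == 1):
        chunk_results = [_run_chunk(j) for j in jobs]
    elif backend in ("process", "auto"):
        with concurrent.futures.ProcessPoolExecutor(
                max_workers=max(1, min(n_workers, len(jobs)))) as pool:
            chunk_results = list(pool.map(_run_chunk, jobs))
    else:
        raise DataError(f"unknown backend {backend!r}")
    return [r for chunk in chunk_results for r in chunk]


# ---------------------------------------------------------------------------
# benchmark metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingTable:
    """Processor count -> elapsed wall-clock seconds, with a baseline."""

    rows: dict[int, float]
    base: int = 4

    def __post_init__(self) -> None:
        if self.base not in self.rows:
            raise DataError(f"baseline processor count {self.base} missing "
                            "from timing table")
        for n, t in self.rows.items():
            if n < 1 or t <= 0:
                raise DataError(f"invalid timing row ({n}, {t})")


def read_timing_table(text: str, base: int = 4) -> TimingTable:
    """Two-column text (processors, seconds); '#' starts a comment."""
    rows = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise DataError(f"expected 'processors seconds', got {line!r}")
        rows[int(parts[0])] = float(parts[1])
    if not rows:
        raise DataError("empty timing table")
    return TimingTable(rows=rows, base=base)


def effective_speedup(t: TimingTable, n: int) -> float:
    """b * t(b) / t(n): processors' worth of perfect scaling delivered."""
    if n not in t.rows:
        raise DataError(f"no timing for {n} processors")
    return t.base * t.rows[t.base] / t.rows[n]


def efficiency(t: TimingTable, n: int) -> float:
    """100 * b * t(b) / (n * t(n)), percent of perfect scaling at n."""
    return 100.0 * effective_speedup(t, n) / n


@dataclass(frozen=True)
class ScalingMetrics:
    n: int
    elapsed: float
    efficiency_pct: float
    effective_processors: float


def benchmark_report(t: TimingTable) -> list[ScalingMetrics]:
    """Per-row scaling metrics, ascending processor count; values are
    unrounded — rounding belongs to presentation."""
    return [ScalingMetrics(n=n, elapsed=t.rows[n],
                           efficiency_pct=efficiency(t, n),
                           effective_processors=effective_speedup(t, n))
            for n in sorted(t.rows)]


def format_benchmark_report(t: TimingTable) -> str:
    rows = benchmark_report(t)
    out = [f"{'procs':>6} {'elapsed_s':>12} {'efficiency_pct':>15} "
           f"{'effective_procs':>16}"]
    for r in rows:
        out.append(f"{r.n:>6d} {r.elapsed:>12.1f} {r.efficiency_pct:>15.1f} "
                   f"{r.effective_processors:>16.1f}")
    return "\n".join(out) + "\n"
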