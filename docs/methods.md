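# Methods

This note records the models, numerical choices and design decisions
behind `phyloboot`, and what the synthetic-data tests do and do not
establish about behaviour on real data.

## Substitution model

All likelihood machinery uses a reversible continuous-time Markov chain
on the 20 amino acids. Given symmetric exchangeabilities `s_ij` and
stationary frequencies `π` (JTT by default; Dayhoff optional — both are
the published empirical tables, embedded as constants in
`phyloboot/_empirical.py`), the generator is

    Q_ij = s_ij π_j   (i ≠ j),   Q_ii = −Σ_{j≠i} Q_ij,

rescaled so that `−Σ_i π_i Q_ii = 1`: branch lengths are expected
replacements per site. Reversibility makes
`A = diag(√π) Q diag(1/√π)` symmetric, so `P(t) = exp(Qt)` is evaluated
through one real eigendecomposition per model, cached at import.
A single rate class is used throughout: no gamma or hidden-Markov rate
variation across sites. That keeps replicate analyses cheap and the
engine surface small, at the cost of underestimating divergence when
rates truly vary — a known, accepted limitation.

Gaps, `?`, and the ambiguity codes B/Z/X are treated as fully missing
everywhere: excluded pairwise in distance estimation, all-ones partial
likelihood vectors in the pruning algorithm, zero-cost-to-any-state
leaf vectors in parsimony. A 21st "deletion" character state was
deliberately not modelled, so the parsimony step matrix stays purely
code-derived.

## Distances

* Observed difference fraction `D` is computed over comparable sites
  only; a pair with no comparable sites is a data error.
* Kimura's correction `d = −ln(1 − D − 0.2 D²)` saturates at
  `D ≈ 0.8541`; saturated pairs yield NaN with a warning rather than an
  exception, so one bad pair cannot abort a thousand-replicate run.
  Tree builders refuse matrices containing NaN.
* The ML pairwise distance maximises `Σ_sites ln(π_a P(t)_ab)` by
  bounded derivative-free search on `t ∈ [10⁻⁹, 20]` with `xatol 1e-8`;
  an optimum pinned at the upper bound is reported as 20 with a
  saturation warning. Identical observable sequences short-circuit to
  exactly 0 (the boundary maximum).

## Parsimony

The replacement cost between amino acids is the minimum number of
amino-acid-changing single-nucleotide steps along codon paths through
the 61 sense codons (synonymous moves are free; stop codons are not
valid intermediates), computed by 0/1-weight Dijkstra from every codon.
One subtlety: serine's two codon families (TCN and AGC/AGT) are not
connected by synonymous moves, so the raw path cost N↔W is 3 while
N→S→W through amino-acid intermediates costs 1+1. Because the Sankoff
dynamic programme assigns amino-acid states to internal nodes, any such
two-hop path is realisable in a reconstruction; the matrix is therefore
closed under the triangle inequality (Floyd–Warshall over the 20
states), making it self-consistent with how it is used. Spot values:
cost(F,L) = 1, cost(F,M) = 2, matrix diameter 3.

Scoring is Sankoff's post-order DP, vectorised across sites; it is
invariant to rooting because the cost matrix is symmetric. Search is
stepwise addition in input order (each new taxon tried on every edge,
ties broken by the deterministic preorder edge index) followed by NNI
hill-climbing, collecting up to `n_best` distinct equally best
topologies. Determinism of every tie-break is what makes parallel runs
worker-count invariant.

## Likelihood

Felsenstein pruning with per-site scaling by the running maximum,
accumulated in log space — alignments beyond ~1,000 sites underflow
naive products, and the three-gene test shapes used here reach 1,139
sites. Branch lengths are clamped to `[10⁻⁸, 100]` and optimised one at
a time by bounded 1-D maximisation, sweeping cyclically until the lnL
gain per sweep drops below `tol` (default 10⁻⁶) or 50 sweeps; the sweep
limit triggers a warning, not an error. A derivative-free optimiser was
chosen over Newton steps for robustness across models; at desk scale
the extra evaluations are immaterial. Topology search starts from
neighbor joining on ML pairwise distances (negative NJ lengths clamped
for the start tree) and accepts any NNI that raises lnL after
re-optimisation, to a local optimum. Equivalence with a more elaborate
search (global rearrangements, random addition orders) is not claimed;
self-consistent local optimality is verified exhaustively at 4 taxa.

Partial-likelihood vectors are retained per node per site during one
tree evaluation and released bottom-up; the implementation targets tens
of taxa by a few thousand sites comfortably in memory.

## Distance trees and consensus

Neighbor joining follows the classic Q-criterion with the standard
branch-length formulas; because `Q[i,j]` and `Q[j,i]` can differ by one
ulp from summation order, tie candidates are canonicalised to `(min,
max)` index pairs before taking the lexicographically lowest — another
determinism guarantee. Negative branch lengths are retained by default
(clamping is an option), which preserves exact additivity: NJ inverts
tree-derived additive matrices to 1e-9, and that inversion is a test.

Bipartitions are stored canonically as the side not containing the
lexicographically smallest taxon, making split sets invariant under
rerooting and rotation. Majority consensus takes splits in strictly
more than half of the input trees (a tie at exactly 50% is excluded,
removing any conflict risk); extended majority then greedily adds
remaining splits in descending frequency, ties in canonical split
order, each accepted only if compatible with everything already kept.
Consensus trees carry percentage support as internal labels and no
branch lengths.

## Resampling and the replicate planner

Bootstrap replicates draw L columns with replacement; delete-half
jackknife keeps `ceil(L/2)` distinct columns in original order; the
permutation test shuffles residues within each column. Replicate `i` is
generated from a counter-derived PRNG substream of `(seed, i)`, so the
stream is a pure function of the seed: chunked parallel generation, or
generating n then m < n replicates, reproduces the serial prefix
exactly. Bit-compatibility with PHYLIP's own resampler is not promised
(different RNG), and the "odd seed" convention is not enforced.

The planner inverts the normal approximation of the binomial error of a
bootstrap proportion: `n = z² p(1−p) / ε²`, `z` the two-sided normal
quantile at the requested coverage, variance maximised at `p = 1/2`
("worst" mode) over the 50–100% support range, and the result rounded
up to the next multiple of 100 — the granularity at which replicate
counts are conventionally quoted. This yields 400 (±5%, 95%), 2,500
(±2%, 95%) and 3,500 (±1% at p = 0.9, 95%). The exact quantile
(1.95996…) versus 1.96 changes no rounded result.

## Parallel execution and scaling metrics

A replicate stream is split into contiguous chunks, one per rank, sizes
differing by at most one (the first `n mod w` ranks get the extra
replicate); empty chunks are legal when workers exceed replicates.
Chunks run under an abstract executor — serial or a process pool —
with identical options, and outputs merge in rank order, never
completion order. Contiguity mirrors sequential file streaming per
worker; rank-ordered merging is what makes the result independent of
the worker count, which the tests check byte-for-byte across 1, 2, 4
and 7 workers for every engine. A failed replicate aborts the run with
its index reported; there is no work stealing or fault tolerance by
design.

Scaling is reported against a baseline core count b (default 4):
`efficiency(n) = 100·b·t(b)/(n·t(n))`, `effective_speedup(n) =
b·t(b)/t(n)`. No rounding happens inside the metrics; presentation
rounds. The package ships three example timing tables
(`phyloboot/data/timings_*.txt`) from 1,000-replicate MPI-parallel runs
of the three engines on large protein families; on the 121-sequence
tables the 64-core distance run delivers 57.7 ≈ 58 effective processors
(90.1% efficiency) and the parsimony run 44.1 ≈ 44 (68.9%). Wall-clock
times themselves are hardware-bound and are inputs here, not outputs.

## Synthetic data: what it does and does not show

The simulator draws root residues from π and propagates them with
`P(t)` per branch — exactly the likelihood model's data-generating
process. Defaults (13 taxa × 375 sites; branch lengths uniform on
[0.02, 0.25]) emulate the shape and divergence regime of a conserved
single-gene protein family, where corrected distances remain estimable.
Tests built on it therefore verify internal correctness (estimators
recover generating parameters; searches find exhaustive optima; every
format round-trips) but cannot detect model misspecification effects —
rate variation across sites, compositional drift, alignment error —
that real alignments carry. The parameter-recovery tolerances (ML
distance within 0.03 of a true 0.3 at 5,000 sites; topology recovery at
6 taxa × 2,000 sites) are set at the sampling-error scale of those
problem sizes, chosen to keep the default test run fast on one CPU.

## Problem sizes used by the checks

Oracle comparisons run at the largest sizes where exhaustive
enumeration is exact and quick: all 105 six-taxon topologies for
parsimony search, all 3 four-taxon topologies (fully re-optimised) for
ML search, brute-force internal-state enumeration at ≤ 6 taxa (Sankoff)
and ≤ 5 taxa (pruning), NJ inversion at ≤ 8 taxa. The pipeline
invariance check uses 20 replicates of a 6-taxon × 80-site alignment;
the stream round-trip uses 1,000 replicates of 13 × 375.
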