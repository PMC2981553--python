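"""Protein maximum likelihood (proml-equivalent), single rate class.

The tree log-likelihood is computed by Felsenstein's pruning algorithm
under a reversible empirical replacement model, with per-site scaling by
the running maximum (accumulated in log space) so alignments of a
thousand sites and more do not underflow.  Branch lengths are optimised
one at a time by bracketed derivative-free maximisation; topology search
starts from a neighbor-joining tree on ML pairwise distances and
hill-climbs through nearest-neighbor interchanges.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .core import (AMINO_ACIDS, DataError, MISSING_RESIDUES, Node,
                   ProteinAlignment, Tree)
from .models import RateModel, get_model

MIN_BRANCH = 1e-8
MAX_BRANCH = 100.0


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic propagator P(t) = exp(Qt) for one branch."""

    P: np.ndarray
    t: float


def transition_probabilities(model: RateModel, t: float) -> TransitionMatrix:
    """exp(Qt) through the model's symmetrised eigendecomposition."""
    return TransitionMatrix(P=model.transition_matrix(t), t=t)


@dataclass
class LikelihoodState:
    """A tree with optimised branch lengths and its log-likelihood."""

    tree: Tree
    model: RateModel
    lnL: float


def _leaf_partials(aln: ProteinAlignment) -> dict[str, np.ndarray]:
    """(L, 20) indicator partials; missing residues are all-ones."""
    out = {}
    for name, seq in zip(aln.names, aln.seqs):
        F = np.zeros((len(seq), 20))
        for s, ch in enumerate(seq):
            if ch in MISSING_RESIDUES:
                F[s, :] = 1.0
            else:
                F[s, AMINO_ACIDS.index(ch)] = 1.0
        out[name] = F
    return out


def _pruning_lnl(tree: Tree, partials: dict[str, np.ndarray],
                 model: RateModel) -> float:
    """Post-order pruning with per-site max scaling in log space."""
    log_scale: Optional[np.ndarray] = None
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            try:
                below[id(node)] = partials[node.name]
            except KeyError:
                raise DataError(f"tree leaf {node.name!r} not in alignment")
            continue
        acc = None
        for ch in node.children:
            t = ch.length if ch.length is not None else MIN_BRANCH
            P = model.transition_matrix(max(t, MIN_BRANCH))
            cond = below.pop(id(ch)) @ P.T
            acc = cond if acc is None else acc * cond
        m = acc.max(axis=1)
        if np.any(m <= 0):
            raise DataError("zero site likelihood: numerically impossible "
                            "site/tree combination")
        acc = acc / m[:, None]
        log_scale = np.log(m) if log_scale is None else log_scale + np.log(m)
        below[id(node)] = acc
    root_part = below[id(tree.root)]
    site_l = root_part @ model.pi
    lnl = float(np.sum(np.log(site_l)) + (log_scale.sum()
                                          if log_scale is not None else 0.0))
    if not np.isfinite(lnl):
        raise DataError("non-finite log-likelihood")
    return lnl


def tree_log_likelihood(tree: Tree, aln: ProteinAlignment,
                        model: Optional[RateModel] = None) -> float:
    """Aggregate log-likelihood of the alignment on the tree."""
    if model is None:
        model = get_model("JTT")
    if set(tree.leaf_names()) != set(aln.names):
        raise DataError("tree leaves and alignment taxa differ")
    return _pruning_lnl(tree, _leaf_partials(aln), model)


def optimize_branch_lengths(tree: Tree, aln: ProteinAlignment,
                            model: Optional[RateModel] = None,
                            tol: float = 1e-6,
                            max_sweeps: int = 50) -> LikelihoodState:
    """Cyclic per-branch maximisation until the lnL gain drops below tol.

    Each branch is optimised by bounded 1-D search on [1e-8, 100] holding
    the others fixed; the aggregate lnL is non-decreasing across sweeps.
    """
    if model is None:
        model = get_model("JTT")
    if set(tree.leaf_names()) != set(aln.names):
        raise DataError("tree leaves and alignment taxa differ")
    t = tree.copy()
    for node in t.postorder():
        if node is not t.root:
            node.length = min(max(node.length or MIN_BRANCH, MIN_BRANCH),
                              MAX_BRANCH)
    partials = _leaf_partials(aln)
    branches = [n for n in t.preorder() if n is not t.root]
    lnl = _pruning_lnl(t, partials, model)
    converged = False
    for _ in range(max_sweeps):
        previous = lnl
        for br in branches:
            old = br.length
            def neg(x: float, _br=br) -> float:
                _br.length = x
                return -_pruning_lnl(t, partials, model)
            res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= lnl:
                br.length = float(res.x)
                lnl = -res.fun
            else:  # optimiser failed to improve: restore the old length
                br.length = old
        if lnl - previous < tol:
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimisation stopped at the sweep "
                      "limit before reaching tol", RuntimeWarning,
                      stacklevel=2)
    return LikelihoodState(tree=t, model=model, lnL=lnl)


def search_ml(replicate: ProteinAlignment,
              model: Optional[RateModel] = None,
              start: Optional[Tree] = None,
              rearrange: str = "nni",
              tol: float = 1e-6) -> LikelihoodState:
    """Maximum-likelihood tree for one replicate.

    Starts from a neighbor-joining tree on ML pairwise distances (or a
    given start tree), optimises branch lengths, then accepts any
    nearest-neighbor interchange that raises the log-likelihood (branch
    lengths re-optimised after each accepted move) until a local optimum.
    """
    from .distances import distance_matrix
    from .parsimony import _nni_neighbors
    from .trees import neighbor_joining

    if model is None:
        model = get_model("JTT")
    if rearrange not in ("none", "nni"):
        raise DataError(f"unknown rearrangement {rearrange!r}")
    if start is None:
        m = distance_matrix(replicate, method="ml", model=model)
        start = neighbor_joining(m, clamp_negative=True)
    state = optimize_branch_lengths(start, replicate, model, tol=tol)
    if rearrange == "none" or replicate.n_taxa < 4:
        return state
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(state.tree):
            cand_state = optimize_branch_lengths(cand, replicate, model,
                                                 tol=tol)
            if cand_state.lnL > state.lnL + 1e-9:
                state = cand_state
                improved = True
                break
    return state
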