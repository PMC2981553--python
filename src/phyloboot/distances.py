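"""Protein distance estimation (protdist-equivalent).

Two corrections of the observed difference fraction D between a pair of
sequences are provided: Kimura's closed form d = -ln(1 - D - D^2/5), and
the maximum-likelihood distance under an empirical replacement model,
found by 1-D optimisation of the pairwise likelihood
sum_sites ln(pi_a P(t)_ab).

Sites where either residue is a gap, '?', or an ambiguity code (B, Z, X)
are dropped pairwise.  A saturated pair (Kimura's log argument
non-positive, or an ML optimum pinned at the upper bound) yields NaN /
the bound with a warning rather than aborting, so a single bad pair
cannot kill a thousand-replicate run.
"""
from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .core import (DataError, DistanceMatrix, MISSING_RESIDUES,
                   ProteinAlignment, UNDEFINED_DISTANCE)
from .models import RateModel, get_model, residue_index

#: D beyond which Kimura's log argument 1 - D - D^2/5 is non-positive
KIMURA_SATURATION = (-1 + math.sqrt(1 + 4 * 0.2)) / (2 * 0.2)

#: upper bound for the ML distance search, substitutions/site
ML_MAX_DISTANCE = 20.0


def _comparable(a: str, b: str) -> list[tuple[str, str]]:
    return [(x, y) for x, y in zip(a, b)
            if x not in MISSING_RESIDUES and y not in MISSING_RESIDUES]


def p_distance(a: str, b: str) -> float:
    """Fraction of comparable sites at which the residues differ."""
    if len(a) != len(b):
        raise DataError("sequences differ in length")
    pairs = _comparable(a.upper(), b.upper())
    if not pairs:
        raise DataError("no comparable sites (all gap/missing/ambiguous)")
    diffs = sum(1 for x, y in pairs if x != y)
    return diffs / len(pairs)


def kimura_distance(a: str, b: str) -> float:
    """Kimura's corrected protein distance, -ln(1 - D - 0.2 D^2).

    Returns NaN (with a warning) when D is at or past saturation.
    """
    D = p_distance(a, b)
    arg = 1.0 - D - 0.2 * D * D
    if arg <= 0.0:
        warnings.warn(f"saturated pair (D={D:.4f}): Kimura distance undefined",
                      RuntimeWarning, stacklevel=2)
        return UNDEFINED_DISTANCE
    return -math.log(arg)


def _pair_counts(a: str, b: str) -> np.ndarray:
    """20x20 table N[i, j] of comparable site pairs (residue i in a, j in b)."""
    N = np.zeros((20, 20))
    for x, y in _comparable(a.upper(), b.upper()):
        N[residue_index(x), residue_index(y)] += 1
    return N


def ml_distance(a: str, b: str, model: Optional[RateModel] = None,
                tol: float = 1e-8) -> float:
    """Maximum-likelihood pairwise distance under an empirical model.

    Maximises sum_sites ln(pi_{a_s} P(t)_{a_s b_s}) over t in
    [0, ML_MAX_DISTANCE] by bracketed 1-D optimisation.  Identical
    sequences sit at the boundary optimum t = 0.
    """
    if model is None:
        model = get_model("JTT")
    N = _pair_counts(a, b)
    if N.sum() == 0:
        raise DataError("no comparable sites (all gap/missing/ambiguous)")
    if np.trace(N) == N.sum():
        return 0.0  # identical observable residues: boundary maximum
    log_pi = np.log(model.pi)

    def neg_loglik(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        ll = np.sum(N * (log_pi[:, None] + np.where(N > 0, logP, 0.0)))
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(1e-9, ML_MAX_DISTANCE),
                          method="bounded", options={"xatol": tol})
    t_hat = float(res.x)
    if t_hat > ML_MAX_DISTANCE * 0.999:
        warnings.warn("pair appears saturated: ML distance at upper bound",
                      RuntimeWarning, stacklevel=2)
        return ML_MAX_DISTANCE
    # collapse to exact zero when the boundary is the optimum
    if t_hat < 1e-7 and neg_loglik(0.0) <= res.fun + 1e-12:
        return 0.0
    return t_hat


def distance_matrix(aln: ProteinAlignment, method: str = "kimura",
                    model: Optional[RateModel] = None) -> DistanceMatrix:
    """All-pairs distance matrix for an alignment.

    method: "kimura" or "ml"; `model` applies to "ml" only (default JTT).
    """
    if method not in ("kimura", "ml"):
        raise DataError(f"unknown distance method {method!r}")
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "kimura":
                v = kimura_distance(aln.seqs[i], aln.seqs[j])
            else:
                v = ml_distance(aln.seqs[i], aln.seqs[j], model=model)
            d[i, j] = d[j, i] = v
    return DistanceMatrix(tuple(aln.names), d)
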