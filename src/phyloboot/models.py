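"""Empirical amino-acid replacement models (JTT, Dayhoff).

A model is a reversible continuous-time Markov chain on the 20 amino
acids, defined by symmetric exchangeabilities s_ij and stationary
frequencies pi: Q_ij = s_ij * pi_j for i != j, rows summing to zero, and
the whole matrix scaled so that -sum_i pi_i Q_ii = 1, i.e. branch lengths
are expected replacements per site.  Reversibility makes
diag(sqrt(pi)) Q diag(1/sqrt(pi)) symmetric, so exp(Qt) is computed once
per model through a real eigendecomposition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _empirical
from .core import AMINO_ACIDS, DataError


@dataclass(frozen=True)
class RateModel:
    """Normalised reversible rate matrix with its spectral factors."""

    name: str
    Q: np.ndarray
    pi: np.ndarray
    # eigendecomposition of diag(sqrt(pi)) Q diag(1/sqrt(pi)):
    # P(t) = right @ diag(exp(lam t)) @ left
    _lam: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, P(0) = identity."""
        if t < 0:
            raise DataError(f"branch length must be non-negative, got {t}")
        P = (self._right * np.exp(self._lam * t)) @ self._left
        np.maximum(P, 0.0, out=P)
        return P


def _build(name: str, exch_lower: tuple, freqs: tuple) -> RateModel:
    n = 20
    S = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            S[i, j] = S[j, i] = exch_lower[k]
            k += 1
    pi = np.asarray(freqs, dtype=float)
    pi = pi / pi.sum()
    Q = S * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))
    Q = Q / mu
    sqrt_pi = np.sqrt(pi)
    A = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    A = (A + A.T) / 2.0  # exactly symmetric despite rounding
    lam, U = np.linalg.eigh(A)
    right = U / sqrt_pi[:, None]
    left = U.T * sqrt_pi[None, :]
    return RateModel(name=name, Q=Q, pi=pi, _lam=lam, _right=right, _left=left)


_JTT = _build("JTT", _empirical.JTT_EXCHANGEABILITIES,
              _empirical.JTT_FREQUENCIES)
_DAYHOFF = _build("DAYHOFF", _empirical.DAYHOFF_EXCHANGEABILITIES,
                  _empirical.DAYHOFF_FREQUENCIES)

_MODELS = {"JTT": _JTT, "DAYHOFF": _DAYHOFF}


def get_model(name: str = "JTT") -> RateModel:
    """Look up a built-in model by name (case-insensitive)."""
    try:
        return _MODELS[name.upper()]
    except KeyError:
        raise DataError(f"unknown model {name!r}; available: "
                        f"{sorted(_MODELS)}") from None


def residue_index(aa: str) -> int:
    """Index of an amino acid in the canonical model ordering."""
    return AMINO_ACIDS.index(aa)
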