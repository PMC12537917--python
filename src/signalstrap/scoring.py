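"""Substitution-matrix scoring schemes and Karlin-Altschul statistics.

The search module emulates the short-query protein search setup practitioners
get from public BLAST servers: PAM30 with affine gap penalties 9/1 and a
permissive E-value cutoff. E-values use the UNGAPPED Karlin-Altschul
parameters applied to gapped scores, a documented approximation: lambda is
the unique positive root of

    sum_ij p_i p_j exp(lambda * s_ij) = 1

for background frequencies p and scores s, and E = K * m * n * exp(-lambda*S).
K defaults to 0.13 and can be re-estimated empirically by shuffle calibration
(see :mod:`signalstrap.synthdata`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AA20, ALPHABET

#: Robinson & Robinson amino-acid background frequencies (per 1000, the
#: composition BLAST uses for protein statistics), keyed by one-letter code.
_ROBINSON_PER_1000 = {
    "A": 78.05, "C": 19.25, "D": 53.64, "E": 62.95, "F": 38.56,
    "G": 73.77, "H": 21.99, "I": 51.42, "K": 57.44, "L": 90.19,
    "M": 22.43, "N": 44.87, "P": 52.03, "Q": 42.64, "R": 51.29,
    "S": 71.20, "T": 58.41, "V": 64.41, "W": 13.30, "Y": 32.16,
}


def robinson_background() -> np.ndarray:
    """Background probabilities over :data:`AA20`, normalised to sum to 1."""
    p = np.array([_ROBINSON_PER_1000[a] for a in AA20], dtype=float)
    return p / p.sum()


def load_matrix(name: str) -> np.ndarray:
    """Load a named substitution matrix as a 21x21 integer array over
    ``ACDEFGHIKLMNPQRSTVWYX``; X scores 0 against everything."""
    m = substitution_matrices.load(name)
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            out[i, j] = int(m[a, b])
    return out


class InvalidScoringError(ValueError):
    """The scoring system admits no Karlin-Altschul statistics."""


def compute_lambda(matrix: np.ndarray, background: np.ndarray,
                   tol: float = 1e-12) -> float:
    """Unique positive root of ``sum p_i p_j exp(lambda s_ij) = 1``.

    ``matrix`` is the 20x20 block over :data:`AA20` (a larger matrix is
    truncated). Found by bracketed bisection; the residual at the returned
    root is below 1e-9 as required for downstream E-values.
    """
    s = np.asarray(matrix, dtype=float)[: len(AA20), : len(AA20)]
    p = np.asarray(background, dtype=float)
    if p.shape != (len(AA20),) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 20 probabilities summing to 1")
    pp = np.outer(p, p)
    expected = float((pp * s).sum())
    if not (s > 0).any():
        raise InvalidScoringError("invalid scoring system: no positive score")
    if expected >= 0:
        raise InvalidScoringError(
            f"invalid scoring system: expected score {expected:.4g} >= 0")

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * s)).sum()) - 1.0

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise InvalidScoringError("failed to bracket lambda")
    # bisection; f(lo) < 0 < f(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol or (hi - lo) < 1e-15:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ScoringScheme:
    """A named substitution matrix with gap penalties and ungapped statistics.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    name: str
    matrix: np.ndarray
    gap_open: float = 9.0
    gap_extend: float = 1.0
    background: np.ndarray = field(default_factory=robinson_background)
    K: float = 0.13
    lambda_u: float = 0.0  # filled by create()

    @classmethod
    def create(cls, name: str = "PAM30", gap_open: float = 9.0,
               gap_extend: float = 1.0, K: float = 0.13,
               background: np.ndarray | None = None,
               matrix: np.ndarray | None = None) -> "ScoringScheme":
        if background is None:
            background = robinson_background()
        if matrix is None:
            matrix = load_matrix(name)
        lam = compute_lambda(matrix, background)
        return cls(name=name, matrix=matrix, gap_open=float(gap_open),
                   gap_extend=float(gap_extend), background=background,
                   K=K, lambda_u=lam)

    def evalue(self, score: float, m: int, n: int) -> float:
        """Karlin-Altschul expectation ``E = K m n exp(-lambda S)``."""
        if m <= 0 or n <= 0:
            raise ValueError("query and database lengths must be positive")
        return self.K * m * n * math.exp(-self.lambda_u * score)

    def bit_score(self, score: float) -> float:
        return (self.lambda_u * score - math.log(self.K)) / math.log(2.0)


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Functional form of :meth:`ScoringScheme.evalue`."""
    return scheme.evalue(score, m, n)
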