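"""Affine-gap local and global alignment.

The local aligner is the in-package stand-in for a blastp-style search
engine: exhaustive Smith-Waterman with affine gaps (a gap of length L costs
``gap_open + L * gap_extend``) and a fully specified traceback tie-break so
results are reproducible to the byte — on ties the traceback prefers
diagonal over up (gap in subject) over left (gap in query), and the
alignment end cell is the lexicographically lowest (row, column) among
maximal cells. Rows index the query, columns the subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .scoring import ScoringScheme
from .seqio import ALPHABET

_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_NEG = -1.0e30


def encode(seq: str) -> np.ndarray:
    """Map a residue string to integer indices over the package alphabet."""
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query and a subject.

    Intervals are 1-based inclusive; ``q_aln``/``s_aln`` are the gapped
    aligned strings; ``identity`` is identical pairs / alignment columns.
    """

    query_id: str
    subject_id: str
    score: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_aln: str
    s_aln: str
    identity: float

    @property
    def length(self) -> int:
        return len(self.q_aln)

    def recomputed_score(self, scheme: ScoringScheme) -> float:
        """Score the reported alignment column by column (audit helper)."""
        return score_alignment(self.q_aln, self.s_aln, scheme)


def score_alignment(q_aln: str, s_aln: str, scheme: ScoringScheme) -> float:
    """Score a gapped alignment independent of any DP matrix."""
    if len(q_aln) != len(s_aln):
        raise ValueError("aligned strings differ in length")
    total = 0.0
    in_gap = False
    for a, b in zip(q_aln, s_aln):
        if a == "-" or b == "-":
            if not in_gap:
                total -= scheme.gap_open
                in_gap = True
            total -= scheme.gap_extend
        else:
            total += scheme.matrix[_INDEX[a], _INDEX[b]]
            in_gap = False
    return total


@njit(cache=False)
def _fill_local(q, s, sub, go, ge):  # pragma: no cover - exercised via wrapper
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)  # gap in query (left moves)
    F = np.full((m + 1, n + 1), _NEG)  # gap in subject (up moves)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - go - ge
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - go - ge
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=False)
def _fill_global(q, s, sub, go, ge):  # pragma: no cover - exercised via wrapper
    m, n = len(q), len(s)
    H = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -go - ge * j
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -go - ge * i
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - go - ge
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - go - ge
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


def _traceback(q: str, s: str, H, E, F, sub, go, ge, i: int, j: int,
               local: bool) -> tuple[str, str, int, int]:
    """Shared traceback. Returns (q_aln, s_aln, q_start, s_start)."""
    qa: list[str] = []
    sa: list[str] = []
    qi, si = encode(q), encode(s)
    while i > 0 or j > 0:
        if local and H[i, j] == 0.0:
            break
        diag = (i > 0 and j > 0 and
                H[i, j] == H[i - 1, j - 1] + sub[qi[i - 1], si[j - 1]])
        if diag:
            qa.append(q[i - 1])
            sa.append(s[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and (j == 0 or H[i, j] == F[i, j]):
            # gap in subject ("up"); walk the F chain, preferring to close it
            while True:
                qa.append(q[i - 1])
                sa.append("-")
                if j == 0:
                    i -= 1
                    if i == 0:
                        break
                elif H[i - 1, j] - go - ge == F[i, j]:
                    i -= 1
                    break
                else:  # extension: F[i, j] == F[i-1, j] - ge
                    i -= 1
        elif j > 0:
            while True:
                qa.append("-")
                sa.append(s[j - 1])
                if i == 0:
                    j -= 1
                    if j == 0:
                        break
                elif H[i, j - 1] - go - ge == E[i, j]:
                    j -= 1
                    break
                else:
                    j -= 1
        else:  # pragma: no cover - unreachable
            break
    return "".join(reversed(qa)), "".join(reversed(sa)), i + 1, j + 1


def smith_waterman(query: str, subject: str, scheme: ScoringScheme,
                   query_id: str = "query", subject_id: str = "subject",
                   evalue: float = float("nan")) -> AlignmentHit | None:
    """Optimal affine-gap local alignment, or ``None`` if the best score <= 0."""
    if not query or not subject:
        raise ValueError("both sequences must be non-empty")
    qi, si = encode(query), encode(subject)
    sub = scheme.matrix.astype(np.float64)
    H, E, F = _fill_local(qi, si, sub, scheme.gap_open, scheme.gap_extend)
    best = float(H.max())
    if best <= 0.0:
        return None
    # lowest (row, column) end cell among maxima
    rows, cols = np.nonzero(H == best)
    order = np.lexsort((cols, rows))
    i, j = int(rows[order[0]]), int(cols[order[0]])
    q_aln, s_aln, q_start, s_start = _traceback(
        query, subject, H, E, F, sub, scheme.gap_open, scheme.gap_extend,
        i, j, local=True)
    matches = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-")
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id, score=best, evalue=evalue,
        q_start=q_start, q_end=i, s_start=s_start, s_end=j,
        q_aln=q_aln, s_aln=s_aln, identity=matches / len(q_aln))


def global_alignment(a: str, b: str, scheme: ScoringScheme) -> tuple[str, str, float]:
    """Needleman-Wunsch with affine gaps; returns (a_aln, b_aln, score)."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    ai, bi = encode(a), encode(b)
    sub = scheme.matrix.astype(np.float64)
    H, E, F = _fill_global(ai, bi, sub, scheme.gap_open, scheme.gap_extend)
    a_aln, b_aln, _, _ = _traceback(
        a, b, H, E, F, sub, scheme.gap_open, scheme.gap_extend,
        len(a), len(b), local=False)
    return a_aln, b_aln, float(H[len(a), len(b)])
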