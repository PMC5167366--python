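"""Smith-Waterman local alignment with affine gap penalties.

Integer scoring against a protein substitution matrix (BLOSUM62 by
default).  A gap of length L costs ``gap_open + L * gap_extend``; with
the defaults (10, 1) the first gapped residue costs 11 and each further
residue 1, matching the common convention of alignment tools.

The traceback is used only to derive the identity fraction of the best
local alignment; the score is the quantity thresholded by the
sequence-similarity mapping operator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import substitution_matrices


@lru_cache(maxsize=4)
def _matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    identity: float  #: identical columns / aligned columns
    query_start: int
    subject_start: int
    length: int  #: aligned columns including gaps


def smith_waterman(
    query: str,
    subject: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 10,
    gap_extend: int = 1,
) -> LocalAlignment:
    """Best local alignment of two protein sequences.

    Returns a zero-score alignment when no positively scoring local
    alignment exists (e.g. an empty sequence).
    """
    sub = _matrix(matrix)
    m, n = len(query), len(subject)
    if m == 0 or n == 0:
        return LocalAlignment(0, 0.0, 0, 0, 0)
    first = gap_open + gap_extend  # cost of opening a gap of length 1

    NEG = -(10 ** 9)
    # H: best score ending at (i, j); E: gap in query (move along subject);
    # F: gap in subject (move along query).  0-based over 1..m, 1..n.
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fp = F[i], F[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Hi[j - 1] - first, Ei[j - 1] - gap_extend)
            Fi[j] = max(Hp[j] - first, Fp[j] - gap_extend)
            try:
                s = int(sub[qi, subject[j - 1]])
            except (IndexError, KeyError, ValueError):
                s = int(sub["X", "X"])
            h = max(0, Hp[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return LocalAlignment(0, 0.0, 0, 0, 0)

    # traceback from (bi, bj) until H hits 0
    i, j = bi, bj
    state = "H"
    ident = 0
    cols = 0
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if h == E[i][j]:
                state = "E"
                continue
            if h == F[i][j]:
                state = "F"
                continue
            cols += 1
            if query[i - 1] == subject[j - 1]:
                ident += 1
            i, j = i - 1, j - 1
        elif state == "E":
            cols += 1
            if E[i][j] == H[i][j - 1] - first:
                state = "H"
            j -= 1
        else:  # F
            cols += 1
            if F[i][j] == H[i - 1][j] - first:
                state = "H"
            i -= 1
    return LocalAlignment(best, ident / cols if cols else 0.0, i, j, cols)


def sw_score(query: str, subject: str, **kw) -> int:
    """Convenience: just the optimal local alignment score."""
    return smith_waterman(query, subject, **kw).score
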