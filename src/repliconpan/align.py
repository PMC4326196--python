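"""Pairwise local alignment (Smith–Waterman with affine gaps, Gotoh recursion).

The protein scoring follows BLASTP defaults (BLOSUM62, gap open 11 / extend 1);
the nucleotide scoring follows BLASTN-style defaults (match +2 / mismatch -3,
gap open 5 / extend 2). A gap of length k costs open + k * extend.

Tie-breaking is fully deterministic and documented so an independent
implementation can reproduce alignments exactly:

* the traceback starts at the best-scoring cell; among equal-scoring cells the
  one with the smallest (i, j) in row-major order wins;
* at each cell the move preference at equal score is diagonal, then vertical
  (gap in the second sequence), then horizontal (gap in the first);
* a gap-open is preferred over a gap-extend when their scores tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # X scored 0 against everything
NUCLEOTIDE_ALPHABET = "ACGTN"  # N scored 0 against everything

NEG_INF = -(10**9)


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0
            else:
                mat[i, j] = int(blosum[a][b])
    return mat


def _nucleotide_matrix(match: int = 2, mismatch: int = -3) -> np.ndarray:
    n = len(NUCLEOTIDE_ALPHABET)
    mat = np.full((n, n), mismatch, dtype=np.int64)
    np.fill_diagonal(mat, match)
    mat[4, :] = 0  # N
    mat[:, 4] = 0
    return mat


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix + affine gap penalties over a fixed alphabet."""

    alphabet: str
    matrix: np.ndarray
    gap_open: int  # penalty for opening a gap (positive)
    gap_extend: int  # penalty per gap position (positive)

    def encode(self, seq: str, name: str = "sequence") -> np.ndarray:
        idx = np.full(128, -1, dtype=np.int8)
        for i, c in enumerate(self.alphabet):
            idx[ord(c)] = i
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        enc = idx[arr]
        bad = np.nonzero(enc < 0)[0]
        if bad.size:
            pos = int(bad[0])
            raise ValueError(f"illegal character {seq[pos]!r} at position {pos} in {name}")
        return enc.astype(np.int8)


PROTEIN_SCORING = Scoring(PROTEIN_ALPHABET, _blosum62_matrix(), gap_open=11, gap_extend=1)
NUCLEOTIDE_SCORING = Scoring(NUCLEOTIDE_ALPHABET, _nucleotide_matrix(), gap_open=5, gap_extend=2)


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one local alignment."""

    score: float
    identity: float  # percent of alignment columns that match
    coverage_a: float  # percent of sequence a spanned by the alignment
    coverage_b: float
    matches: int
    alignment_length: int
    a_span: tuple[int, int]  # 1-based inclusive aligned span on a (0,0 if empty)
    b_span: tuple[int, int]


@njit(cache=False)
def _sw_kernel(a, b, sub, gap_open, gap_ext):  # pragma: no cover - numba
    la = a.shape[0]
    lb = b.shape[0]
    open_cost = gap_open + gap_ext

    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    E = np.full((la + 1, lb + 1), NEG_INF, dtype=np.int64)  # gap in a (consumes b)
    F = np.full((la + 1, lb + 1), NEG_INF, dtype=np.int64)  # gap in b (consumes a)
    # pointers: ptrH 0=stop 1=diag 2=F(vertical) 3=E(horizontal)
    ptrH = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrE = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0=open from H, 1=extend
    ptrF = np.zeros((la + 1, lb + 1), dtype=np.int8)

    best = 0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e_open = H[i, j - 1] - open_cost
            e_ext = E[i, j - 1] - gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1

            f_open = H[i - 1, j] - open_cost
            f_ext = F[i - 1, j] - gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1

            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    # traceback
    matches = 0
    aln_len = 0
    i = bi
    j = bj
    a_end = bi
    b_end = bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in a, consume b[j-1]
            aln_len += 1
            nxt = ptrE[i, j]
            j -= 1
            if nxt == 0:
                state = 0
        else:  # F: gap in b, consume a[i-1]
            aln_len += 1
            nxt = ptrF[i, j]
            i -= 1
            if nxt == 0:
                state = 0
    a_start = i + 1
    b_start = j + 1
    if best == 0:
        a_start = a_end = b_start = b_end = 0
    return best, matches, aln_len, a_start, a_end, b_start, b_end


def align_pair(seq_a: str, seq_b: str, scoring: Scoring = PROTEIN_SCORING) -> AlignmentResult:
    """Locally align two sequences; report identity, per-sequence coverage
    and raw score.

    Identity is matches / alignment columns x 100 over the optimal local
    alignment; coverage of a sequence is the aligned span on that sequence
    over its full length x 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    a = scoring.encode(seq_a, "sequence a")
    b = scoring.encode(seq_b, "sequence b")
    score, matches, aln_len, a1, a2, b1, b2 = _sw_kernel(
        a, b, scoring.matrix, scoring.gap_open, scoring.gap_extend
    )
    if aln_len == 0:
        return AlignmentResult(0.0, 0.0, 0.0, 0.0, 0, 0, (0, 0), (0, 0))
    identity = 100.0 * matches / aln_len
    cov_a = 100.0 * (a2 - a1 + 1) / len(seq_a)
    cov_b = 100.0 * (b2 - b1 + 1) / len(seq_b)
    return AlignmentResult(
        score=float(score),
        identity=identity,
        coverage_a=cov_a,
        coverage_b=cov_b,
        matches=int(matches),
        alignment_length=int(aln_len),
        a_span=(int(a1), int(a2)),
        b_span=(int(b1), int(b2)),
    )
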