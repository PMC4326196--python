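"""Independent quadratic-space Smith-Waterman (Gotoh) oracle.

A deliberately plain pure-Python dynamic program used only to cross-check the
production aligner. It follows the same published conventions (BLOSUM62 /
match-mismatch scoring, affine gaps costing open + k * extend, and the
documented deterministic tie-breaks: best cell at smallest (i, j); move
preference diagonal > vertical > horizontal; gap-open preferred over extend
on ties) but shares no code with the production kernel.
"""

from __future__ import annotations

NEG = float("-inf")


def oracle_align(seq_a, seq_b, score_fn, gap_open, gap_extend):
    """Return (score, matches, alignment_length, a_span, b_span)."""
    la, lb = len(seq_a), len(seq_b)
    open_cost = gap_open + gap_extend

    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    ptrH = [[0] * (lb + 1) for _ in range(la + 1)]  # 0 stop, 1 diag, 2 vert, 3 horiz
    ptrE = [[0] * (lb + 1) for _ in range(la + 1)]  # 0 open, 1 extend
    ptrF = [[0] * (lb + 1) for _ in range(la + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e_open = H[i][j - 1] - open_cost
            e_ext = E[i][j - 1] - gap_extend
            if e_open >= e_ext:
                E[i][j], ptrE[i][j] = e_open, 0
            else:
                E[i][j], ptrE[i][j] = e_ext, 1
            f_open = H[i - 1][j] - open_cost
            f_ext = F[i - 1][j] - gap_extend
            if f_open >= f_ext:
                F[i][j], ptrF[i][j] = f_open, 0
            else:
                F[i][j], ptrF[i][j] = f_ext, 1

            h, p = 0.0, 0
            diag = H[i - 1][j - 1] + score_fn(seq_a[i - 1], seq_b[j - 1])
            if diag > h:
                h, p = diag, 1
            if F[i][j] > h:
                h, p = F[i][j], 2
            if E[i][j] > h:
                h, p = E[i][j], 3
            H[i][j], ptrH[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j

    matches = aln_len = 0
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            p = ptrH[i][j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if seq_a[i - 1] == seq_b[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            aln_len += 1
            nxt = ptrE[i][j]
            j -= 1
            if nxt == 0:
                state = "H"
        else:
            aln_len += 1
            nxt = ptrF[i][j]
            i -= 1
            if nxt == 0:
                state = "H"
    if best == 0:
        return 0.0, 0, 0, (0, 0), (0, 0)
    return best, matches, aln_len, (i + 1, bi), (j + 1, bj)


def blosum62_score_fn():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")

    def score(a, b):
        if a == "X" or b == "X":
            return 0.0
        return float(mat[a][b])

    return score


def nucleotide_score_fn(match=2.0, mismatch=-3.0):
    def score(a, b):
        if a == "N" or b == "N":
            return 0.0
        return match if a == b else mismatch

    return score


def oracle_identity_coverage(seq_a, seq_b, score_fn, gap_open, gap_extend):
    score, matches, aln_len, a_span, b_span = oracle_align(
        seq_a, seq_b, score_fn, gap_open, gap_extend
    )
    if aln_len == 0:
        return score, 0.0, 0.0, 0.0
    identity = 100.0 * matches / aln_len
    cov_a = 100.0 * (a_span[1] - a_span[0] + 1) / len(seq_a)
    cov_b = 100.0 * (b_span[1] - b_span[0] + 1) / len(seq_b)
    return score, identity, cov_a, cov_b
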