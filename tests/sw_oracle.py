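"""Independent brute-force Smith-Waterman oracle for the test suite.

A deliberately simple quadratic-space dynamic program with explicit H/E/F
matrices and a recomputing traceback, kept structurally different from the
package's numba kernel so agreement between the two is meaningful.  Only
intended for short sequences (<= ~100 nt).
"""

from __future__ import annotations

NEG = -(10**9)


def oracle_sw(query: str, subject: str, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Return (score, q_start, q_end, s_start, s_end, matches, columns) of the
    best local alignment, or None if the best score is 0.

    Gap of length k costs gap_open + k*gap_extend.  Ties: the best cell with
    the smallest (q_end, s_end); moves prefer diagonal over up over left.
    """
    m, n = len(query), len(subject)
    oe = gap_open + gap_extend

    def sub(a, b):
        a, b = a.upper(), b.upper()
        return match if (a == b and a in "ACGT") else mismatch

    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - oe, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - oe, F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + sub(query[i - 1], subject[j - 1]), E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return None

    # traceback, recomputing the decision at each cell with the tie policy
    i, j, state = bi, bj, "H"
    matches = columns = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + sub(query[i - 1], subject[j - 1])
            if H[i][j] == diag:
                columns += 1
                if query[i - 1].upper() == subject[j - 1].upper() and query[i - 1].upper() in "ACGT":
                    matches += 1
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            columns += 1
            opened = H[i - 1][j] - oe >= F[i - 1][j] - gap_extend
            i -= 1
            if opened:
                state = "H"
        else:
            columns += 1
            opened = H[i][j - 1] - oe >= E[i][j - 1] - gap_extend
            j -= 1
            if opened:
                state = "H"
    return best, i, bi, j, bj, matches, columns
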