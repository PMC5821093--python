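"""Independent quadratic-DP alignment oracles for small instances.

Plain Gotoh dynamic programming (three-state affine gaps), written without
reference to the package's alignment code, for cross-checking scores and
hit coordinates on sequences of a few hundred residues.  A gap of length L
scores ``open + (L - 1) * extend`` (the opening score includes the first
gapped position).
"""

from __future__ import annotations

NEG = float("-inf")


def smith_waterman(
    query: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    open_gap: float = -5.0,
    extend_gap: float = -2.0,
):
    """Best local alignment: returns (score, (q_start, q_end), (r_start, r_end)).

    Traceback follows the highest-scoring cell; ties resolve to the
    lowest (i, j) end cell, which matches leftmost-start hits on the
    unambiguous planted instances used in tests.
    """
    n, m = len(query), len(ref)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consume ref)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (consume query)
    back = {}
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_gap, E[i][j - 1] + extend_gap)
            F[i][j] = max(H[i - 1][j] + open_gap, F[i - 1][j] + extend_gap)
            s = match if query[i - 1] == ref[j - 1] else mismatch
            diag = H[i - 1][j - 1] + s
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h > 0:
                if h == diag:
                    back[(i, j)] = (i - 1, j - 1)
                elif h == E[i][j]:
                    back[(i, j)] = (i, j - 1)
                else:
                    back[(i, j)] = (i - 1, j)
            if h > best:
                best, best_cell = h, (i, j)
    if best_cell is None:
        return 0.0, (0, 0), (0, 0)
    i, j = best_cell
    qi, rj = i, j
    while (i, j) in back and H[i][j] > 0:
        i, j = back[(i, j)]
    return best, (i, qi), (j, rj)


def semiglobal_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    open_gap: float = -5.0,
    extend_gap: float = -2.0,
) -> float:
    """Optimal global alignment score with free end gaps on both sequences."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_gap, E[i][j - 1] + extend_gap)
            F[i][j] = max(H[i - 1][j] + open_gap, F[i - 1][j] + extend_gap)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if i == 1 and j == 1:
                H[i][j] = max(H[i][j], s)
    # free trailing end gap: best over the last row and last column
    return max(
        max(H[n][j] for j in range(m + 1)),
        max(H[i][m] for i in range(n + 1)),
    )
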