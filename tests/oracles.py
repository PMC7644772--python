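"""Independent oracles used by the tests.

The local-alignment oracle is a hand-written Gotoh dynamic program
(numba-accelerated) sharing no code with the package's alignment path;
it returns the best local score plus the match/column counts of one
optimal traceback under the same scoring scheme (match +1, mismatch -1,
gap open -2 covering the first gap column, extend -1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode(), dtype=np.uint8).astype(np.int64)


@njit(cache=False)
def _fill_local(t, q, match, mismatch, gap_open, gap_ext):
    n, m = t.shape[0], q.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)  # gap in query (vertical)
    F = np.full((n + 1, m + 1), NEG, np.int64)  # gap in target (horizontal)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i - 1, j] + gap_open, E[i - 1, j] + gap_ext)
            f = max(H[i, j - 1] + gap_open, F[i, j - 1] + gap_ext)
            s = match if t[i - 1] == q[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            h = max(h, e)
            h = max(h, f)
            h = max(h, 0)
            E[i, j], F[i, j], H[i, j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


@njit(cache=False)
def _traceback_local(t, q, H, E, F, bi, bj, match, mismatch, gap_open, gap_ext):
    """Counts (matches, columns) of one optimal local traceback.

    Diagonal moves are preferred, then vertical, then horizontal, which
    matches the usual high-road convention.
    """
    i, j = bi, bj
    matches = columns = 0
    state = 0  # 0=H, 1=E(vertical), 2=F(horizontal)
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if i > 0 and j > 0 and t[i - 1] == q[j - 1] else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                columns += 1
                if t[i - 1] == q[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if E[i, j] == E[i - 1, j] + gap_ext:
                i -= 1
            else:
                i -= 1
                state = 0
        else:
            columns += 1
            if F[i, j] == F[i, j - 1] + gap_ext:
                j -= 1
            else:
                j -= 1
                state = 0
    return matches, columns


def local_alignment_oracle(
    target: str,
    query: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_ext: int = -1,
) -> tuple[int, int, int]:
    """(score, matches, columns) of the best local alignment."""
    t, q = _codes(target), _codes(query)
    H, E, F, best, bi, bj = _fill_local(t, q, match, mismatch, gap_open, gap_ext)
    if best <= 0:
        return 0, 0, 0
    matches, columns = _traceback_local(
        t, q, H, E, F, bi, bj, match, mismatch, gap_open, gap_ext
    )
    return int(best), int(matches), int(columns)


def best_identity_oracle(
    read_bases: str, references: list[str], min_aligned_length: int = 30
) -> float:
    """Best identity of a read over references and both strands,
    mirroring the fishing contract but computed by the independent DP."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = read_bases.translate(comp)[::-1]
    best_score, best_ident = NEG, 0.0
    for ref in references:
        ref_ungapped = ref.replace("-", "").replace("?", "")
        for query in (read_bases, rc):
            score, matches, columns = local_alignment_oracle(ref_ungapped, query)
            if score > best_score:
                ident = matches / columns if columns else 0.0
                if columns < min_aligned_length:
                    ident = 0.0
                best_score, best_ident = score, ident
    return best_ident


def tn93_oracle(a: str, b: str, gamma_shape: float | None = None) -> float:
    """Separately coded Tamura-Nei closed form from observed proportions.

    Counts the two transition classes, transversions and pooled base
    frequencies directly from the strings, then evaluates the published
    formula; independent of the package's vectorised implementation.
    """
    import math

    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    n = len(pairs)
    P1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    Q = sum(1 for x, y in pairs if x != y) / n - P1 - P2
    pool = [x for p in pairs for x in p]
    gA = pool.count("A") / len(pool)
    gC = pool.count("C") / len(pool)
    gG = pool.count("G") / len(pool)
    gT = pool.count("T") / len(pool)
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        return float("nan")
    if gamma_shape is None:
        return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    s = gamma_shape
    return (
        k1 * s * (w1 ** (-1 / s) - 1)
        + k2 * s * (w2 ** (-1 / s) - 1)
        + k3 * s * (w3 ** (-1 / s) - 1)
    )
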