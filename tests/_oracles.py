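"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: MEMs are enumerated
by scanning every diagonal, the local aligner is a full
Smith-Waterman dynamic program (numba-compiled), and N50 is a brute
scan over candidate lengths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_mems(a: str, b: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal exact matches >= min_len, by diagonal scanning.

    Returned as (q_start, t_start, length, strand) with '-' meaning
    a[qs:qs+L] == rc(b[ts:ts+L]); N matches nothing.
    """

    def fwd(a: str, b: str) -> set[tuple[int, int, int]]:
        out = set()
        la, lb = len(a), len(b)
        for d in range(-(lb - 1), la):  # diagonal: i - j = d
            i = max(d, 0)
            j = i - d
            run = 0
            while i <= la and j <= lb:
                if i < la and j < lb and a[i] == b[j] and a[i] != "N":
                    run += 1
                else:
                    if run >= min_len:
                        out.add((i - run, j - run, run))
                    run = 0
                i += 1
                j += 1
        return out

    mems = {(i, j, L, "+") for i, j, L in fwd(a, b)}
    rb = rc(b)
    n = len(b)
    for i, j, L in fwd(a, rb):
        mems.add((i, n - j - L, L, "-"))
    return mems


_ENC = np.zeros(128, dtype=np.int8)
for _i, _c in enumerate("ACGT", start=1):
    _ENC[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """A=1 C=2 G=3 T=4, N=0 (never matches)."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw(a, b, match, mismatch, gap):
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros((la + 1, lb + 1), dtype=np.int32)
    best = 0
    bi = bj = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 0) else mismatch
            h = H[i - 1, j - 1] + s
            if H[i - 1, j] + gap > h:
                h = H[i - 1, j] + gap
            if H[i, j - 1] + gap > h:
                h = H[i, j - 1] + gap
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    # traceback (diagonal preferred) counting matches and columns
    i, j = bi, bj
    matches = 0
    columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 0) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == match:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, i, bi, j, bj, matches, columns


def sw_local(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Optimal local alignment of a vs b.

    Returns (score, q_start, q_end, t_start, t_end, identity) with
    half-open intervals.
    """
    score, q0, q1, t0, t1, matches, columns = _sw(
        encode(a), encode(b), match, mismatch, gap
    )
    identity = matches / columns if columns else 0.0
    return score, q0, q1, t0, t1, identity


def brute_n50(lengths) -> int:
    """Largest L among the lengths with sum(l for l >= L) >= total/2."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = max(best, L)
    return best
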