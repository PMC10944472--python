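"""Edit-distance primitives for barcode design and matching.

Myers' bit-parallel algorithm gives Levenshtein distances for the short
(15 nt) barcode strings orders of magnitude faster than a plain DP, which
matters when a whole barcode set is checked pairwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["levenshtein", "hamming", "min_pairwise_edit", "hamming_matrix"]


def levenshtein(a: str, b: str) -> int:
    """Exact Levenshtein distance via Myers' bit-parallel algorithm.

    Assumes ``len(a) <= 64`` (true for all barcode/motif uses here); falls
    back to the classic DP otherwise.
    """
    if len(a) > len(b):
        a, b = b, a
    m = len(a)
    if m == 0:
        return len(b)
    if m > 64:
        return _levenshtein_dp(a, b)
    peq: dict[str, int] = {}
    for i, ch in enumerate(a):
        peq[ch] = peq.get(ch, 0) | (1 << i)
    pv = (1 << m) - 1
    mv = 0
    score = m
    high = 1 << (m - 1)
    for ch in b:
        eq = peq.get(ch, 0)
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | ~(xh | pv)
        mh = pv & xh
        if ph & high:
            score += 1
        if mh & high:
            score -= 1
        ph = (ph << 1) | 1
        pv = (mh << 1) | ~(xv | ph)
        mv = ph & xv
        pv &= (1 << m) - 1
        mv &= (1 << m) - 1
    return score


def _levenshtein_dp(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_edit(seqs: list[str]) -> int:
    """Minimum Levenshtein distance over all pairs (exhaustive)."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    best = max(len(s) for s in seqs)
    for i in range(len(seqs)):
        si = seqs[i]
        for j in range(i + 1, len(seqs)):
            d = levenshtein(si, seqs[j])
            if d < best:
                best = d
                if best == 0:
                    return 0
    return best


def hamming_matrix(query: str, pool: np.ndarray) -> np.ndarray:
    """Hamming distances between ``query`` and byte-encoded rows of ``pool``.

    ``pool`` is a (n, L) uint8 array of ASCII codes. 'N' in the query counts
    as a mismatch against everything (undetermined base).
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    if q.shape[0] != pool.shape[1]:
        raise ValueError("query length does not match pool width")
    return (pool != q[None, :]).sum(axis=1)
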