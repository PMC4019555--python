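"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the seeding/extension machinery of the package:
exact repeats are found by run-length scanning boolean match arrays on every
(anti-)diagonal, and tree distances are recomputed by path traversal.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len as (start, length)."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def brute_force_exact_pairs(
    seq: str, min_len: int, L: int, inverted: bool = False
) -> set[tuple]:
    """All maximal exact repeat pairs of length >= min_len.

    ``seq`` may carry a circular overhang beyond ``L``; pairs are
    canonicalized modulo ``L`` exactly like the detector output so the two
    sets are directly comparable: ((start, end, wraps), (start, end, wraps)).
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    found: set[tuple] = set()

    def canon(s0: int, ln: int) -> tuple:
        start = s0 % L + 1
        wraps = (s0 % L) + ln > L
        end = (s0 + ln - 1) % L + 1
        return (start, end, wraps)

    def emit(a0: int, b0: int, ln: int) -> None:
        ka, kb = canon(a0, ln), canon(b0, ln)
        if ka == kb:
            return
        found.add((min(ka, kb), max(ka, kb)))

    if not inverted:
        for d in range(1, n):
            if d % L == 0:
                continue
            m = arr[: n - d] == arr[d:]
            for s, ln in _runs(m, min_len):
                emit(s, s + d, ln)
    else:
        comp = np.frombuffer(seq.translate(_COMP).encode(), dtype=np.uint8)
        for c in range(n + n - 1):
            lo = max(0, c - n + 1)
            hi = min(c, n - 1)
            idx = np.arange(lo, hi + 1)
            m = arr[idx] == comp[c - idx]
            for s, ln in _runs(m, min_len):
                a0 = lo + s
                b0 = c - (a0 + ln - 1)
                if b0 > a0:
                    emit(a0, b0, ln)
    return found


def pairwise_identity_brute(seq_a: str, seq_b: str) -> float:
    """Ungapped percent identity for equal-length sequences (test fixtures)."""
    assert len(seq_a) == len(seq_b)
    matches = sum(1 for x, y in zip(seq_a, seq_b) if x == y)
    return 100.0 * matches / len(seq_a)
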