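"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: plain substring scans,
a quadratic semi-global edit-distance DP, and a full-matrix Gotoh DP, all
under the same mask-intersection match rule the aligner uses.
"""

from __future__ import annotations

import numpy as np


def brute_occurrences(text: str, pattern: str) -> list[int]:
    """All (overlapping) start offsets of pattern in text."""
    out, i = [], text.find(pattern)
    while i >= 0:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def semiglobal_mask_distance(tg: np.ndarray, qg: np.ndarray) -> int:
    """Minimal unit-cost differences aligning all of qg inside tg.

    Free target start and end; a column matches when the masks intersect.
    """
    m, n = len(qg), len(tg)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            match = 0 if (int(tg[j - 1]) & int(qg[i - 1])) else 1
            cur[j] = min(prev[j - 1] + match, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def gotoh_mask_score(tg: np.ndarray, qg: np.ndarray, a: int, b: int, o: int, e: int) -> int:
    """Optimal local-alignment score with affine gaps, full-matrix recurrences."""
    n, m = len(tg), len(qg)
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - o, E[i, j - 1]) - e
            F[i, j] = max(H[i - 1, j] - o, F[i - 1, j]) - e
            s = a if (int(tg[i - 1]) & int(qg[j - 1])) else b
            H[i, j] = max(H[i - 1, j - 1] + s, E[i, j], F[i, j], 0)
            if H[i, j] > best:
                best = int(H[i, j])
    return best


def random_mask_pair(rng: np.random.Generator, m_max: int = 60, *, widen_frac: float = 0.1,
                     plant: bool = True, e_pad: int | None = None):
    """A random (target, query) Gray-mask instance, usually with a planted hit."""
    m = int(rng.integers(1, m_max))
    if e_pad is None:
        n = int(rng.integers(1, m_max + 20))
    else:
        n = m + 2 * e_pad
    tg = np.left_shift(1, rng.integers(0, 4, n)).astype(np.uint8)
    qg = np.left_shift(1, rng.integers(0, 4, m)).astype(np.uint8)
    wide = rng.random(n) < widen_frac
    if wide.any():
        tg[wide] |= np.left_shift(1, rng.integers(0, 4, int(wide.sum()))).astype(np.uint8)
    if plant and rng.random() < 0.6 and n >= m:
        s = int(rng.integers(0, n - m + 1))
        tg[s : s + m] = qg
        for _ in range(int(rng.integers(0, 4))):
            p = int(rng.integers(0, m))
            tg[s + p] = 1 << int(rng.integers(0, 4))
    return tg, qg
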