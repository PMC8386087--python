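"""SNP-aware pairwise extension: snpLCE, snpLV, and snpSW.

All three operate on Gray-encoded sequences: 4-bit allele masks, one per
position, where target position i and query position j *match* iff
``tg[i] & qg[j] != 0``.  On one-hot masks this reduces to character equality,
so snpLV is classic unit-cost Landau–Vishkin edit-distance extension and
snpSW is classic Smith–Waterman with Gotoh affine gaps; the widened masks at
panel positions are exactly what makes known SNPs free.

snpLV treats the problem as semi-global: the query (read) must be consumed
in full, while the target (a reference slab padded by ``e_max`` on each
side) has a free start and end.  States live on diagonals
``d = target_pos - query_pos``; ``L[d, e]`` is the furthest query index
reached on diagonal d with e differences, and every advance ends with a
longest-common-extension jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reference_model import SnpPanel

CigarOp = tuple[str, int]

_QUERY_CONSUMING = {"M", "I", "S", "=", "X"}
_TARGET_CONSUMING = {"M", "D", "=", "X"}


def cigar_to_string(cigar: Sequence[CigarOp]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) or "*"


def _push(cigar: list[CigarOp], op: str, n: int) -> None:
    if n <= 0:
        return
    if cigar and cigar[-1][0] == op:
        cigar[-1] = (op, cigar[-1][1] + n)
    else:
        cigar.append((op, n))


def snp_lce(tg: np.ndarray, qg: np.ndarray, ti: int, qi: int) -> int:
    """Longest common extension under the mask-intersection match rule.

    Largest L with ``(tg[ti+x] & qg[qi+x]) != 0`` for all x < L; stops at
    either sequence end.
    """
    n = min(len(tg) - ti, len(qg) - qi)
    if n <= 0:
        return 0
    v = tg[ti : ti + n] & qg[qi : qi + n]
    misses = np.nonzero(v == 0)[0]
    return int(misses[0]) if misses.size else n


@dataclass
class LvAlignment:
    edit_distance: int
    cigar: list[CigarOp]
    target_start: int   # 0-based offset of the alignment start within tg
    target_end: int


def snp_lv(tg: np.ndarray, qg: np.ndarray, e_max: int) -> LvAlignment | None:
    """SNP-aware Landau–Vishkin k-difference extension with traceback.

    Returns the minimal-difference semi-global alignment of the full query
    ``qg`` inside the target slab ``tg`` (unit-cost substitutions,
    insertions, deletions; mask-intersection matches are free), or None if
    no alignment with at most ``e_max`` differences exists.  Ties between
    predecessor cases prefer substitution over deletion over insertion.
    """
    m, n = len(qg), len(tg)
    if m == 0:
        return LvAlignment(0, [], 0, 0)
    if n == 0:
        return None
    # L[e][d] -> furthest query index; back[(e, d)] -> (op, prev_d, j_before, j_after_op)
    # An alignment with <= e_max differences consumes >= m - e_max target
    # symbols, so its start diagonal d0 satisfies d0 <= n - m + e_max.
    layer: dict[int, int] = {}
    back: dict[tuple[int, int], tuple[str, int, int, int]] = {}
    d_hi = min(n - 1, n - m + e_max)
    for d in range(0, d_hi + 1):
        layer[d] = snp_lce(tg, qg, d, 0)
        if layer[d] == m:
            return _lv_traceback(back, 0, d, m)
    if e_max == 0 or not layer:
        return None
    for e in range(1, e_max + 1):
        new_layer: dict[int, int] = {}
        cand_ds = set()
        for d in layer:
            cand_ds.update((d - 1, d, d + 1))
        for d in sorted(cand_ds):
            best_j = -1
            best = None  # (op, prev_d, j_before, j_after_op)
            # preference on ties: substitution > deletion > insertion.
            # States always satisfy pj + pd >= 0 (paths start at d >= 0 and
            # never move the target cursor backwards), so only upper bounds
            # need guarding.
            for op, pd in (("X", d), ("D", d - 1), ("I", d + 1)):
                pj = layer.get(pd)
                if pj is None:
                    continue
                if op == "X":       # consume query pj and target pj + d
                    if pj >= m or pj + d >= n:
                        continue
                    j = pj + 1
                elif op == "D":     # consume target pj + d - 1 only
                    if pj + d - 1 >= n:
                        continue
                    j = pj
                else:               # 'I': consume query pj only
                    if pj >= m:
                        continue
                    j = pj + 1
                if j > best_j:
                    best_j = j
                    best = (op, pd, pj, j)
            if best is None:
                continue
            j = best_j
            if j < m:
                j += snp_lce(tg, qg, j + d, j)
            prev = new_layer.get(d)
            if prev is None or j > prev:
                new_layer[d] = j
                back[(e, d)] = best
        layer = new_layer
        if not layer:
            return None
        done = sorted(d for d, j in layer.items() if j == m)
        if done:
            return _lv_traceback(back, e, done[0], m)
    return None


def _lv_traceback(back, e, d, m) -> LvAlignment:
    """Rebuild the CIGAR from the per-(e, d) predecessor records."""
    cigar_rev: list[CigarOp] = []
    j = m
    dist = e
    while e > 0:
        op, pd, j_before, j_after = back[(e, d)]
        _push(cigar_rev, "M", j - j_after)            # the LCE run
        if op == "X":
            _push(cigar_rev, "M", 1)
        elif op == "I":
            _push(cigar_rev, "I", 1)
        else:
            _push(cigar_rev, "D", 1)
        j = j_before
        d = pd
        e -= 1
    _push(cigar_rev, "M", j)                           # e = 0 leading matches
    cigar = list(reversed([c for c in cigar_rev]))
    # merge adjacent same ops after reversal
    merged: list[CigarOp] = []
    for op, n in cigar:
        _push(merged, op, n)
    t_start = d
    t_end = t_start + sum(n for op, n in merged if op in _TARGET_CONSUMING)
    return LvAlignment(dist, merged, t_start, t_end)


@dataclass(frozen=True)
class SwScoring:
    """Affine-gap local alignment scores: match a, mismatch b, gap open o, extend e."""

    a: int = 1
    b: int = -4
    o: int = 6
    e: int = 1

    def __post_init__(self):
        if not (self.a > 0 >= self.b) or self.o < 0 or self.e < 0:
            raise ValueError("require a > 0 >= b and o, e >= 0")


@dataclass
class SwAlignment:
    score: int
    cigar: list[CigarOp]       # with soft clips at the query ends
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    n_diff: int                # mismatching + gapped columns in the aligned region


def snp_sw(tg: np.ndarray, qg: np.ndarray, scoring: SwScoring = SwScoring()) -> SwAlignment:
    """SNP-aware local alignment (Smith–Waterman with Gotoh affine gaps).

    Substitution score is ``a`` when the masks intersect and ``b`` otherwise.
    The traceback starts from the highest-scoring cell (ties to the smallest
    target then query index) and stops at the first zero cell; unaligned
    query ends become soft clips.
    """
    n, m = len(tg), len(qg)
    if m == 0 or n == 0:
        return SwAlignment(0, ([("S", m)] if m else []), 0, 0, 0, 0, 0)
    NEG = -(10**9)
    a, b, o, e = scoring.a, scoring.b, scoring.o, scoring.e
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    F_row = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    # pointers: for H, 0=stop,1=diag,2=E(ins),3=F(del); for E/F: 1 if extended
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    sub = np.where((tg[:, None] & qg[None, :]) != 0, a, b).astype(np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        # F (gap in query == target consumed == deletion) vectorises per row
        open_f = H[i - 1] - o - e
        ext_f = F_row[i - 1] - e
        F = np.maximum(open_f, ext_f)
        ptr_f[i] = (ext_f >= open_f).astype(np.uint8)
        F_row[i] = F
        Hrow = H[i]
        Hprev = H[i - 1]
        srow = sub[i - 1]
        Ej = NEG
        for j in range(1, m + 1):
            open_e = Hrow[j - 1] - o - e
            ext_e = Ej - e
            Ej = ext_e if ext_e >= open_e else open_e
            ptr_e[i, j] = 1 if ext_e >= open_e else 0
            diag = Hprev[j - 1] + srow[j - 1]
            h = diag
            p = 1
            if Ej > h:
                h, p = Ej, 2
            if F[j] > h:
                h, p = F[j], 3
            if h <= 0:
                h, p = 0, 0
            Hrow[j] = h
            ptr_h[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return SwAlignment(0, [("S", m)], 0, 0, 0, 0, 0)
    # traceback
    i, j = bi, bj
    cigar_rev: list[CigarOp] = []
    n_diff = 0
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                _push(cigar_rev, "M", 1)
                if sub[i - 1, j - 1] != a:
                    n_diff += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":   # insertion: query consumed
            _push(cigar_rev, "I", 1)
            n_diff += 1
            if ptr_e[i, j] == 0:
                state = "H"
            j -= 1
        else:                # deletion: target consumed
            _push(cigar_rev, "D", 1)
            n_diff += 1
            if ptr_f[i, j] == 0:
                state = "H"
            i -= 1
    cigar: list[CigarOp] = []
    _push(cigar, "S", j)
    for op, cnt in reversed(cigar_rev):
        _push(cigar, op, cnt)
    _push(cigar, "S", m - bj)
    return SwAlignment(best, cigar, i, bi, j, bj, n_diff)


@dataclass
class AlignmentResult:
    """One placed alignment of a read on the primary reference."""

    chrom: str
    pos: int                 # 0-based leftmost reference position
    strand: str              # '+' | '-'
    cigar: list[CigarOp]     # M/I/D/S, query-consuming ops sum to read length
    edit_distance: int       # SNP-aware differences (snpLV) / diff count (snpSW)
    method: str              # 'snpLV' | 'snpSW'
    score: int | None = None
    snp_ids_used: tuple[str, ...] = ()

    @property
    def end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in _TARGET_CONSUMING)

    def query_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)


def snp_ids_from_traceback(aln: AlignmentResult, panel: SnpPanel, oriented_read: str) -> tuple[str, ...]:
    """Panel ids at aligned columns where the read carries an ALT allele.

    ``oriented_read`` must be the read as aligned (reverse-complemented for
    minus-strand alignments).  Sites where the read shows the reference
    allele do not count.
    """
    ids = []
    t, q = aln.pos, 0
    for op, n in aln.cigar:
        if op in ("M", "=", "X"):
            for x in range(n):
                rec = panel.get(aln.chrom, t + x)
                if rec is not None and oriented_read[q + x] in rec.alt_alleles:
                    ids.append(rec.snp_id)
            t += n
            q += n
        elif op in ("I", "S"):
            q += n
        elif op == "D":
            t += n
    return tuple(ids)
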