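"""FM-indexes over the primary reference (CFM) and alternative reference (RFM).

Both are plain Burrows–Wheeler-transform indexes with a full suffix array and
uncompressed per-symbol occurrence tables — the memory engineering of
production aligners is deliberately absent at this scale.  The RFM-index adds
the structure that makes SNP-aware seeding possible: ALT-REF suffixes that
begin with ``#`` are anchored in *primary genome* coordinates, so any match
inside an alternative window can be projected back onto the linear reference
by walking to the preceding window boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reference_model import (
    AltReference,
    GenomeSequence,
    SnpPanel,
    SnpRecord,
    WindowAnchor,
)

SERIAL_VERSION = "salt-index-1"


@dataclass(frozen=True)
class SaInterval:
    """Half-open suffix-array rank interval for a matched pattern."""

    low: int
    high: int
    pattern_length: int

    @property
    def width(self) -> int:
        return self.high - self.low

    @property
    def empty(self) -> bool:
        return self.high <= self.low


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling; ``codes`` must end with a unique 0."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.zeros(n, dtype=np.int64)
        if k < n:
            key2[:-k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 1
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n:
            return order.astype(np.int64)
        k *= 2


class FmIndex:
    """FM-index (BWT + C + Occ + full SA) over a small alphabet.

    The sentinel ``$`` is appended internally and ordered before every other
    symbol.  Backward search of a pattern containing a symbol outside the
    alphabet yields an empty interval rather than an error.
    """

    def __init__(self, text: str, alphabet: str):
        if not text:
            raise ValueError("cannot index an empty text")
        if "$" in alphabet:
            raise ValueError("'$' is reserved for the sentinel")
        bad = set(text) - set(alphabet)
        if bad:
            raise ValueError(f"text symbol(s) {sorted(bad)!r} outside alphabet {alphabet!r}")
        self.alphabet = "$" + alphabet
        self.text = text
        self._code = {c: i for i, c in enumerate(self.alphabet)}
        sigma = len(self.alphabet)
        lut = np.zeros(128, dtype=np.uint8)
        for c, i in self._code.items():
            lut[ord(c)] = i
        self._lut = lut
        codes = lut[np.frombuffer((text + "$").encode("ascii"), dtype=np.uint8)]
        self.text_length = len(codes)
        sa = _suffix_array(codes)
        self.sa = sa
        bwt = codes[sa - 1]  # sa==0 wraps to codes[-1] == '$'
        self.bwt_codes = bwt
        # counts C[c] = number of symbols strictly smaller than c
        hist = np.bincount(codes, minlength=sigma)
        self.counts = np.concatenate([[0], np.cumsum(hist)[:-1]]).astype(np.int64)
        # occ[i, c] = occurrences of c in bwt[:i]
        occ = np.zeros((self.text_length + 1, sigma), dtype=np.int64)
        one_hot = np.zeros((self.text_length, sigma), dtype=np.int64)
        one_hot[np.arange(self.text_length), bwt] = 1
        occ[1:] = np.cumsum(one_hot, axis=0)
        self.occ = occ

    @property
    def bwt(self) -> str:
        return "".join(self.alphabet[c] for c in self.bwt_codes)

    def lf(self, row: int) -> int:
        c = self.bwt_codes[row]
        return int(self.counts[c] + self.occ[row, c])

    def reconstruct_text(self) -> str:
        """Invert the BWT via the LF walk (uses only bwt/C/Occ, not the text)."""
        out = []
        row = 0  # row of the '$' suffix; bwt there is the last text symbol
        for _ in range(self.text_length - 1):
            out.append(self.alphabet[self.bwt_codes[row]])
            row = self.lf(row)
        return "".join(reversed(out))

    def backward_search(self, pattern: str) -> SaInterval:
        """SA interval of ``pattern``; empty interval if absent or off-alphabet."""
        m = len(pattern)
        if m == 0:
            raise ValueError("empty pattern")
        lo, hi = 0, self.text_length
        for ch in reversed(pattern):
            c = self._code.get(ch)
            if c is None or c == 0:
                return SaInterval(0, 0, m)
            lo = int(self.counts[c] + self.occ[lo, c])
            hi = int(self.counts[c] + self.occ[hi, c])
            if lo >= hi:
                return SaInterval(0, 0, m)
        return SaInterval(lo, hi, m)

    def occurrences(self, iv: SaInterval) -> np.ndarray:
        """Sorted text offsets for an interval."""
        if iv.empty:
            return np.zeros(0, dtype=np.int64)
        return np.sort(self.sa[iv.low : iv.high])


def build_fm_index(text: str, alphabet: str) -> FmIndex:
    return FmIndex(text, alphabet)


class CfmIndex:
    """FM-index over the concatenated primary contigs.

    Contigs are concatenated without separators; ``locate`` drops hits whose
    span crosses a contig boundary (artifacts of the concatenation).  The
    text alphabet admits N so references with Ns index cleanly, but patterns
    containing N always miss.
    """

    def __init__(self, contigs: Sequence[GenomeSequence]):
        if not contigs:
            raise ValueError("no contigs")
        self.contigs = list(contigs)
        self.names = [g.name for g in contigs]
        starts = np.cumsum([0] + [g.length for g in contigs])
        self.starts = starts[:-1]
        self.ends = starts[1:]
        text = "".join(g.seq for g in contigs)
        alphabet = "ACGT" + ("N" if "N" in text else "")
        self.fm = FmIndex(text, alphabet)

    def backward_search(self, pattern: str) -> SaInterval:
        # N never participates in a match, even though text Ns are indexed
        if not set(pattern) <= set("ACGT"):
            return SaInterval(0, 0, len(pattern))
        return self.fm.backward_search(pattern)

    def locate(self, iv: SaInterval) -> list[tuple[str, int]]:
        """(chrom, 0-based pos) per occurrence, sorted, boundary hits dropped."""
        out = []
        for g in self.fm.occurrences(iv):
            ci = int(np.searchsorted(self.ends, g, side="right"))
            if g + iv.pattern_length <= self.ends[ci]:
                out.append((self.names[ci], int(g - self.starts[ci])))
        return out


class RfmIndex:
    """FM-index over ALT-REF with '#'-suffixes anchored in primary coordinates."""

    def __init__(self, alt: AltReference):
        if not alt.text:
            raise ValueError("empty alternative reference")
        self.alt = alt
        self.fm = FmIndex(alt.text, "#ACGT")
        # '#' at text offset q terminates window i and precedes window i+1
        anchor_by_hashpos: dict[int, int] = {}
        off = 0
        for i, a in enumerate(alt.anchors):
            q = off + a.length
            if i + 1 < len(alt.anchors):
                anchor_by_hashpos[q] = i + 1
            off = q + 1
        self._anchor_by_hashpos = anchor_by_hashpos

    def backward_search(self, pattern: str) -> SaInterval:
        return self.fm.backward_search(pattern)

    def alt_locate(self, iv: SaInterval) -> list[tuple[str, int, int]]:
        """Project occurrences onto primary coordinates.

        For each occurrence, walk backward with LF-mapping counting steps s
        until the preceding symbol is '#' (or the '$' sentinel, which bounds
        the first window); the match lies at offset s inside the window that
        follows, so its primary coordinate is the window anchor start + s.
        Returns sorted, deduplicated (chrom, pos, window_id).
        """
        if iv.empty:
            return []
        fm = self.fm
        hash_code = fm._code["#"]
        results = set()
        for row in range(iv.low, iv.high):
            r, s = row, 0
            while True:
                c = fm.bwt_codes[r]
                if c == hash_code:
                    q = int(fm.sa[fm.lf(r)])
                    win = self._anchor_by_hashpos[q]
                    break
                if c == 0:  # '$': text start bounds the first window
                    if not self.alt.anchors:
                        raise RuntimeError("LF walk hit '$' with no windows")
                    win = 0
                    break
                r = fm.lf(r)
                s += 1
            a = self.alt.anchors[win]
            if s + iv.pattern_length > a.length:
                raise RuntimeError("match crosses a '#' boundary")  # unreachable for ACGT patterns
            results.add((a.chrom, a.start + s, win))
        return sorted(results)


class IndexBundle:
    """The pair of indexes plus the panel and reference they were built from."""

    def __init__(
        self,
        contigs: Sequence[GenomeSequence],
        panel: SnpPanel,
        k: int,
        cfm: CfmIndex | None = None,
        alt: AltReference | None = None,
        rfm: RfmIndex | None = None,
    ):
        from .reference_model import build_alt_reference

        self.contigs = list(contigs)
        self.panel = panel
        self.k = k
        self.cfm = cfm or CfmIndex(contigs)
        self.alt = alt if alt is not None else build_alt_reference(contigs, panel, k)
        if rfm is not None:
            self.rfm = rfm
        else:
            self.rfm = RfmIndex(self.alt) if self.alt.n_windows else None

    def contig(self, name: str) -> GenomeSequence:
        return next(g for g in self.contigs if g.name == name)

    def save(self, prefix: str) -> str:
        """Serialize to ``<prefix>.salt.npz`` (bit-exact round trip)."""
        meta = {
            "version": SERIAL_VERSION,
            "k": self.k,
            "contigs": [{"name": g.name, "seq": g.seq} for g in self.contigs],
            "panel": [
                {
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref_allele,
                    "alts": list(r.alt_alleles),
                    "id": r.snp_id,
                }
                for r in self.panel
            ],
            "alt_text": self.alt.text,
            "anchors": [
                {"chrom": a.chrom, "start": a.start, "length": a.length, "ids": list(a.snp_ids)}
                for a in self.alt.anchors
            ],
        }
        path = f"{prefix}.salt.npz"
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
            cfm_sa=self.cfm.fm.sa,
            rfm_sa=self.rfm.fm.sa if self.rfm else np.zeros(0, dtype=np.int64),
        )
        return path

    @classmethod
    def load(cls, prefix: str) -> "IndexBundle":
        path = prefix if prefix.endswith(".salt.npz") else f"{prefix}.salt.npz"
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta["version"] != SERIAL_VERSION:
            raise ValueError(f"unsupported index version {meta['version']!r}")
        contigs = [GenomeSequence(c["name"], c["seq"]) for c in meta["contigs"]]
        panel = SnpPanel(
            [
                SnpRecord(r["chrom"], r["pos"], r["ref"], tuple(r["alts"]), r["id"])
                for r in meta["panel"]
            ]
        )
        alt = AltReference(
            text=meta["alt_text"],
            anchors=[
                WindowAnchor(a["chrom"], a["start"], a["length"], tuple(a["ids"]))
                for a in meta["anchors"]
            ],
        )
        cfm = CfmIndex(contigs)
        rfm = RfmIndex(alt) if alt.n_windows else None
        return cls(contigs, panel, meta["k"], cfm=cfm, alt=alt, rfm=rfm)
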