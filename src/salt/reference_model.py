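"""Reference genome, SNP panel, allele bitmasks, and the alternative reference.

The aligner augments a linear reference genome with a panel of known SNPs.
Two derived structures are built here:

* a *Gray-encoded* reference: one 4-bit mask per position, one bit per
  nucleotide (A,C,G,T from most- to least-significant), with the bit set
  when that nucleotide is a known allele at the site.  A read base matches a
  reference site iff the two masks intersect, so known alternative alleles
  never count as differences during extension.
* the *alternative reference* (ALT-REF): for every panel SNP, all haplotype
  strings over the window centred on the SNP that carry at least one
  alternative allele, concatenated with ``#`` separators.  Indexing this text
  lets seeds that straddle an alternative allele be found exactly.
"""

from __future__ import annotations

import itertools
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"
#: bit per nucleotide, A most-significant through T least-significant
BASE_BIT = {"A": 0b1000, "C": 0b0100, "G": 0b0010, "T": 0b0001, "N": 0b0000}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: one-hot mask per ASCII code, used to vectorise encoding
_CODE_LUT = np.zeros(128, dtype=np.uint8)
for _b, _m in BASE_BIT.items():
    _CODE_LUT[ord(_b)] = _m


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def mask_to_bits(mask: int) -> str:
    """Render a 4-bit allele mask as its binary digit string, e.g. 0b0011 -> '0011'."""
    return format(int(mask), "04b")


def mask_of_alleles(alleles: Iterable[str]) -> int:
    m = 0
    for a in alleles:
        m |= BASE_BIT[a]
    return m


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig of the primary reference, upper-case over {A,C,G,T,N}."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


def load_fasta(path) -> list[GenomeSequence]:
    """Load a FASTA file into a list of contigs, in file order.

    Sequences are upper-cased; any character outside {A,C,G,T,N} is a parse
    error reporting the record and offset.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = next((i for i, c in enumerate(seq) if c not in "ACGTN"), None)
        if bad is not None:
            raise ValueError(
                f"{path}: record {rec.id!r} has invalid character {seq[bad]!r} "
                f"at position {bad + 1}"
            )
        out.append(GenomeSequence(rec.id, seq))
    return out


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic-or-more SNP at a 0-based primary coordinate."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    snp_id: str

    def __post_init__(self):
        if self.ref_allele not in BASES:
            raise ValueError(f"bad ref allele {self.ref_allele!r}")
        if not self.alt_alleles or not (set(self.alt_alleles) <= set(BASES)):
            raise ValueError(f"bad alt alleles {self.alt_alleles!r}")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("ref allele repeated among alts")

    @property
    def mask(self) -> int:
        return mask_of_alleles((self.ref_allele,) + self.alt_alleles)


class SnpPanel:
    """Validated SNP records, sorted by (chrom, pos), unique per position."""

    def __init__(self, records: Sequence[SnpRecord]):
        self.records: list[SnpRecord] = sorted(
            records, key=lambda r: (r.chrom, r.pos)
        )
        self._by_chrom: dict[str, list[int]] = {}
        self._rec_by_chrom: dict[str, list[SnpRecord]] = {}
        for r in self.records:
            self._by_chrom.setdefault(r.chrom, []).append(r.pos)
            self._rec_by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, poss in self._by_chrom.items():
            if len(set(poss)) != len(poss):
                raise ValueError(f"duplicate panel positions on {chrom}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, chrom: str, pos: int) -> SnpRecord | None:
        poss = self._by_chrom.get(chrom)
        if not poss:
            return None
        i = bisect_left(poss, pos)
        if i < len(poss) and poss[i] == pos:
            return self._rec_by_chrom[chrom][i]
        return None

    def in_range(self, chrom: str, start: int, end: int) -> list[SnpRecord]:
        """Panel records with start <= pos < end on one contig."""
        poss = self._by_chrom.get(chrom)
        if not poss:
            return []
        lo = bisect_left(poss, start)
        hi = bisect_right(poss, end - 1)
        return self._rec_by_chrom[chrom][lo:hi]


def load_snp_panel(path, ref: Sequence[GenomeSequence]) -> SnpPanel:
    """Load a SNP panel from a 5-column TSV or an uncompressed VCF.

    TSV columns: chrom, pos (1-based), ref, alt (comma-separated), id.
    Positions are converted to 0-based.  Records whose ref allele disagrees
    with the genome are dropped (counted in a warning); indel records are
    skipped (SNPs only); an unknown contig is an error.  Records at the same
    position merge their alternative alleles.
    """
    by_name = {g.name: g for g in ref}
    rows = _read_panel_rows(path)
    merged: dict[tuple[str, int], dict] = {}
    dropped = skipped = 0
    for chrom, pos1, ref_a, alts, snp_id in rows:
        if chrom not in by_name:
            raise ValueError(f"{path}: unknown contig {chrom!r}")
        ref_a = ref_a.upper()
        alts = [a.upper() for a in alts]
        if len(ref_a) != 1 or any(len(a) != 1 for a in alts):
            skipped += 1  # indel / MNV rows are out of scope
            continue
        if ref_a not in BASES or not all(a in BASES for a in alts):
            skipped += 1
            continue
        pos = pos1 - 1
        g = by_name[chrom]
        if pos < 0 or pos >= g.length or g.seq[pos] != ref_a:
            dropped += 1
            continue
        alt_set = {a for a in alts if a != ref_a}
        if not alt_set:
            skipped += 1
            continue
        key = (chrom, pos)
        if key in merged:
            merged[key]["alts"] |= alt_set
        else:
            merged[key] = {"ref": ref_a, "alts": set(alt_set), "id": snp_id}
    if dropped:
        logger.warning("%s: dropped %d record(s) failing ref-allele check", path, dropped)
    if skipped:
        logger.warning("%s: skipped %d non-SNP record(s)", path, skipped)
    records = [
        SnpRecord(chrom, pos, v["ref"], tuple(sorted(v["alts"])), v["id"])
        for (chrom, pos), v in merged.items()
    ]
    return SnpPanel(records)


def _read_panel_rows(path):
    """Yield (chrom, pos1, ref, alts, id) from TSV or VCF."""
    text = open(path).read()
    is_vcf = text.startswith("##fileformat=VCF") or str(path).endswith(".vcf")
    rows = []
    if is_vcf:
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                alts = [a for a in (rec.alts or ())]
                rows.append((rec.chrom, rec.pos, rec.ref or "", alts, rec.id or f"{rec.chrom}:{rec.pos}"))
        return rows
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ValueError(f"{path}:{lineno}: expected 5 TSV columns, got {len(parts)}")
        chrom, pos_s, ref_a, alt_s, snp_id = parts[:5]
        rows.append((chrom, int(pos_s), ref_a, alt_s.split(","), snp_id))
    return rows


def encode_gray(ref: GenomeSequence, panel: SnpPanel) -> np.ndarray:
    """4-bit allele mask per reference position (uint8 array).

    Non-SNP sites are one-hot; panel sites carry the union mask of the
    reference and alternative alleles; N encodes as 0000 and never matches.
    """
    codes = _CODE_LUT[np.frombuffer(ref.seq.encode("ascii"), dtype=np.uint8)].copy()
    for rec in panel.in_range(ref.name, 0, ref.length):
        codes[rec.pos] = rec.mask
    return codes


def encode_read_gray(read: str) -> np.ndarray:
    """One-hot 4-bit mask per read base; N -> 0000 (never matches)."""
    if not read:
        return np.zeros(0, dtype=np.uint8)
    arr = np.frombuffer(read.upper().encode("ascii"), dtype=np.uint8)
    if np.any(_CODE_LUT[arr] == 0) and not set(read.upper()) <= set("ACGTN"):
        bad = next(c for c in read.upper() if c not in "ACGTN")
        raise ValueError(f"invalid base {bad!r} in read")
    return _CODE_LUT[arr].copy()


@dataclass(frozen=True)
class WindowAnchor:
    """Primary-coordinate anchor of one ALT-REF window."""

    chrom: str
    start: int  # 0-based primary coordinate of the window's first base
    length: int
    snp_ids: tuple[str, ...]  # panel ids whose ALT allele the window carries


@dataclass
class AltReference:
    """'#'-joined alternative windows plus their coordinate anchors.

    ``text`` is every window followed by '#' (the text ends in '#');
    ``anchors[i]`` describes the i-th window.
    """

    text: str
    anchors: list[WindowAnchor] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.anchors)

    def window_text(self, i: int) -> str:
        start = sum(a.length + 1 for a in self.anchors[:i])
        return self.text[start : start + self.anchors[i].length]


DEFAULT_WINDOW_HALF_WIDTH = 21
MAX_COMBINATIONS_PER_SITE = 256


def build_alt_reference(
    ref: Sequence[GenomeSequence],
    panel: SnpPanel,
    k: int = DEFAULT_WINDOW_HALF_WIDTH,
    max_combinations: int = MAX_COMBINATIONS_PER_SITE,
) -> AltReference:
    """Enumerate SNP-window haplotypes and join them with '#'.

    For each panel SNP at position p, every haplotype over the window
    [p-k, p+k] (clipped at contig ends) obtained by choosing one allele at p
    and at every other panel SNP inside the window is emitted, except the
    all-reference combination (already indexed by the primary FM-index).
    SNPs are incorporated nearest-the-centre first; once the number of
    combinations would exceed ``max_combinations`` the remaining SNPs in the
    window are fixed to their reference allele (with a warning).  Windows
    overlapping N are skipped; duplicate (anchor, string) windows arising
    from adjacent sites are emitted once.
    """
    if k < 1:
        raise ValueError("window half-width k must be >= 1")
    by_name = {g.name: g for g in ref}
    windows: list[tuple[str, WindowAnchor]] = []
    seen: set[tuple[str, int, str]] = set()
    for site in panel:
        g = by_name[site.chrom]
        start = max(0, site.pos - k)
        end = min(g.length, site.pos + k + 1)
        base = g.seq[start:end]
        if "N" in base:
            continue
        in_win = panel.in_range(site.chrom, start, end)
        # nearest-the-centre first, ties to the left
        in_win = sorted(in_win, key=lambda r: (abs(r.pos - site.pos), r.pos))
        chosen: list[SnpRecord] = []
        combos = 1
        for r in in_win:
            nxt = combos * (1 + len(r.alt_alleles))
            if nxt > max_combinations:
                logger.warning(
                    "%s:%d: capped haplotype enumeration at %d combinations",
                    site.chrom, site.pos, max_combinations,
                )
                break
            chosen.append(r)
            combos = nxt
        choice_sets = [(r.ref_allele,) + r.alt_alleles for r in chosen]
        for picks in itertools.product(*choice_sets):
            ids = tuple(
                r.snp_id
                for r, a in zip(chosen, picks)
                if a != r.ref_allele
            )
            if not ids:  # all-reference haplotype: covered by the primary index
                continue
            hap = list(base)
            for r, a in zip(chosen, picks):
                hap[r.pos - start] = a
            hap_s = "".join(hap)
            key = (site.chrom, start, hap_s)
            if key in seen:
                continue
            seen.add(key)
            windows.append(
                (hap_s, WindowAnchor(site.chrom, start, len(hap_s), tuple(sorted(ids))))
            )
    text = "".join(w + "#" for w, _ in windows)
    return AltReference(text=text, anchors=[a for _, a in windows])
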