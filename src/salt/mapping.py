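"""Per-read orchestration: seed, extend, filter, pair, rescue, emit SAM.

Single-end flow: candidate loci from both indexes are extended with snpLV
against a Gray-encoded reference slab; the best alignment and its ties are
kept, everything with a SNP-aware edit distance above 10% of the read length
is discarded, and survivors are written as SAM with NM/AS tags plus a ZS tag
listing the panel SNP ids whose alternative allele the read carries.

Paired-end flow adds the insert-size window [u - 3*sigma, u + 3*sigma]:
hit pairs in forward–reverse orientation inside the window become proper
pairs; a mate that failed to align on its own is rescued by SNP-aware local
alignment inside the window implied by its anchored partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from . import __version__
from .extension import (
    AlignmentResult,
    SwScoring,
    cigar_to_string,
    snp_ids_from_traceback,
    snp_lv,
    snp_sw,
)
from .index import IndexBundle
from .reference_model import encode_gray, encode_read_gray, revcomp
from .seeding import SeedingConfig, collect_candidates, generate_seeds

MAX_READ_LENGTH = 10_000
SNP_ID_TAG = "ZS"
POLISH_FAIL_TAG = "ZP"


@dataclass(frozen=True)
class ReadRecord:
    name: str
    seq: str
    quals: str | None = None
    mate_index: int | None = None  # 1 | 2 | None

    def __post_init__(self):
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(f"{self.name}: SEQ/QUAL length mismatch")


@dataclass(frozen=True)
class PairConstraint:
    """Insert-size model; the accept window is [u - 3*sigma, u + 3*sigma]."""

    u: float = 400.0
    sigma: float = 50.0

    @property
    def min_distance(self) -> int:
        return int(self.u - 3 * self.sigma)

    @property
    def max_distance(self) -> int:
        return int(self.u + 3 * self.sigma)


@dataclass
class MappingConfig:
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    scoring: SwScoring = field(default_factory=SwScoring)
    max_diff_frac: float = 0.10   # output filter: NM <= floor(frac * read length)
    pair: PairConstraint = field(default_factory=PairConstraint)
    emit_secondary: bool = True
    rescue_score_frac: float = 0.5


def compute_mapq(best: float, second_best: float | None, n_ties: int) -> int:
    """Heuristic mapping quality (not part of the alignment model).

    0 when the best score is tied; 60 for a unique hit with no runner-up;
    otherwise min(60, 6 * (best - second_best)).
    """
    if n_ties > 1:
        return 0
    if second_best is None:
        return 60
    return max(0, min(60, int(6 * (best - second_best))))


class _GraySlabCache:
    """Gray-encoded contigs, built lazily once per contig."""

    def __init__(self, bundle: IndexBundle):
        self.bundle = bundle
        self._cache: dict[str, np.ndarray] = {}

    def contig_masks(self, chrom: str) -> np.ndarray:
        if chrom not in self._cache:
            g = self.bundle.contig(chrom)
            self._cache[chrom] = encode_gray(g, self.bundle.panel)
        return self._cache[chrom]

    def slab(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, int]:
        masks = self.contig_masks(chrom)
        start = max(0, start)
        end = min(len(masks), end)
        return masks[start:end], start


@dataclass
class MappedRead:
    """All surviving alignments of one read; empty means unmapped."""

    read: ReadRecord
    alignments: list[AlignmentResult]
    mapq: int = 0

    @property
    def mapped(self) -> bool:
        return bool(self.alignments)

    @property
    def primary(self) -> AlignmentResult | None:
        return self.alignments[0] if self.alignments else None


def align_single(
    read: ReadRecord,
    bundle: IndexBundle,
    cfg: MappingConfig = None,
    slabs: _GraySlabCache | None = None,
) -> MappedRead:
    """Seed-and-extend one read; keep the best alignment plus ties.

    Alignments with SNP-aware edit distance above ``max_diff_frac`` of the
    read length are never emitted; a read with no surviving alignment is
    reported unmapped.
    """
    cfg = cfg or MappingConfig()
    if len(read.seq) > MAX_READ_LENGTH:
        raise ValueError(f"{read.name}: read longer than {MAX_READ_LENGTH} bp (short-read scope)")
    slabs = slabs or _GraySlabCache(bundle)
    seq = read.seq.upper()
    e_max = int(cfg.max_diff_frac * len(seq))
    seeds = generate_seeds(seq, bundle.cfm, bundle.rfm, cfg.seeding)
    candidates = collect_candidates(seeds, bundle.cfm, bundle.rfm)
    oriented = {"+": seq, "-": revcomp(seq)}
    qgrays = {s: encode_read_gray(o) for s, o in oriented.items()}
    results: dict[tuple[str, int, str], AlignmentResult] = {}
    for cand in candidates:
        qg = qgrays[cand.strand]
        tg, slab_start = slabs.slab(
            cand.chrom, cand.diag_pos - e_max, cand.diag_pos + len(seq) + e_max
        )
        lv = snp_lv(tg, qg, e_max)
        if lv is None:
            continue
        pos = slab_start + lv.target_start
        res = AlignmentResult(
            chrom=cand.chrom,
            pos=pos,
            strand=cand.strand,
            cigar=lv.cigar,
            edit_distance=lv.edit_distance,
            method="snpLV",
            score=-lv.edit_distance,
        )
        key = (res.chrom, res.pos, res.strand)
        if key not in results or res.edit_distance < results[key].edit_distance:
            results[key] = res
    ranked = sorted(
        results.values(), key=lambda r: (r.edit_distance, r.chrom, r.pos, r.strand)
    )
    ranked = [r for r in ranked if r.edit_distance <= e_max]
    if not ranked:
        return MappedRead(read, [])
    best_nm = ranked[0].edit_distance
    ties = [r for r in ranked if r.edit_distance == best_nm]
    runner_up = next((r for r in ranked if r.edit_distance > best_nm), None)
    for r in ties:
        r.snp_ids_used = snp_ids_from_traceback(r, bundle.panel, oriented[r.strand])
    mapq = compute_mapq(
        -best_nm, None if runner_up is None else -runner_up.edit_distance, len(ties)
    )
    kept = ties if cfg.emit_secondary else ties[:1]
    return MappedRead(read, kept, mapq)


def pair_hits(
    hits1: MappedRead, hits2: MappedRead, pc: PairConstraint, read_len2: int | None = None
) -> tuple[AlignmentResult, AlignmentResult] | None:
    """Best properly-oriented pair within the insert window, else None.

    Orientation must be forward–reverse with the forward alignment leftmost;
    the distance is outer (leftmost start to rightmost end).  Among accepted
    combinations the best combined score wins, ties broken by coordinate.
    """
    best = None
    for a1 in hits1.alignments:
        for a2 in hits2.alignments:
            if a1.chrom != a2.chrom or a1.strand == a2.strand:
                continue
            fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
            if fwd.pos > rev.pos:
                continue
            d = rev.end - fwd.pos
            if not (pc.min_distance <= d <= pc.max_distance):
                continue
            combined = (a1.score or 0) + (a2.score or 0)
            key = (-combined, a1.chrom, a1.pos, a2.pos)
            if best is None or key < best[0]:
                best = (key, (a1, a2))
    return best[1] if best else None


def mate_rescue(
    anchored: AlignmentResult,
    mate: ReadRecord,
    pc: PairConstraint,
    bundle: IndexBundle,
    cfg: MappingConfig = None,
    slabs: _GraySlabCache | None = None,
) -> AlignmentResult | None:
    """SNP-aware local alignment of an unmapped mate inside the pair window.

    Accepted when the local score reaches ``rescue_score_frac * a * |mate|``.
    """
    cfg = cfg or MappingConfig()
    slabs = slabs or _GraySlabCache(bundle)
    L = len(mate.seq)
    if anchored.strand == "+":
        lo = anchored.pos + pc.min_distance - L
        hi = anchored.pos + pc.max_distance
        mate_strand = "-"
    else:
        lo = anchored.end - pc.max_distance
        hi = anchored.end - pc.min_distance + L
        mate_strand = "+"
    tg, win_start = slabs.slab(anchored.chrom, lo, hi)
    if len(tg) == 0:
        return None
    oriented = mate.seq.upper() if mate_strand == "+" else revcomp(mate.seq.upper())
    qg = encode_read_gray(oriented)
    sw = snp_sw(tg, qg, cfg.scoring)
    if sw.score < cfg.rescue_score_frac * cfg.scoring.a * L:
        return None
    res = AlignmentResult(
        chrom=anchored.chrom,
        pos=win_start + sw.target_start,
        strand=mate_strand,
        cigar=sw.cigar,
        edit_distance=sw.n_diff,
        method="snpSW",
        score=sw.score,
    )
    res.snp_ids_used = snp_ids_from_traceback(res, bundle.panel, oriented)
    return res


# ---------------------------------------------------------------- SAM output


def sam_header(bundle_contigs, command_line: str = "salt") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g.name, "LN": g.length} for g in bundle_contigs],
            "PG": [{"ID": "salt", "PN": "salt", "VN": __version__, "CL": command_line}],
        }
    )


def _to_segment(
    header: pysam.AlignmentHeader,
    read: ReadRecord,
    aln: AlignmentResult | None,
    mapq: int,
    *,
    secondary: bool = False,
    paired: bool = False,
    proper: bool = False,
    mate: tuple[str, int, str, bool] | None = None,  # (chrom, pos, strand, unmapped)
    tlen: int = 0,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.name
    flag = 0
    if paired:
        flag |= 0x1
        flag |= 0x40 if read.mate_index == 1 else 0x80
        if proper:
            flag |= 0x2
    seq, quals = read.seq.upper(), read.quals
    if aln is None:
        flag |= 0x4
        seg.flag = flag
        seg.query_sequence = seq
        if quals:
            seg.query_qualities = pysam.qualitystring_to_array(quals)
        if mate is not None:
            _set_mate(seg, mate, header)
            seg.flag = seg.flag | flag
        return seg
    if aln.strand == "-":
        flag |= 0x10
        seq = revcomp(seq)
        quals = quals[::-1] if quals else None
    if secondary:
        flag |= 0x100
    seg.flag = flag
    seg.reference_id = header.get_tid(aln.chrom)
    seg.reference_start = aln.pos
    seg.mapping_quality = mapq if not secondary else 0
    seg.cigarstring = cigar_to_string(aln.cigar)
    seg.query_sequence = seq
    if quals:
        seg.query_qualities = pysam.qualitystring_to_array(quals)
    tags = [("NM", int(aln.edit_distance)), ("AS", int(aln.score or 0))]
    if aln.snp_ids_used:
        tags.append((SNP_ID_TAG, ",".join(aln.snp_ids_used)))
    seg.set_tags(tags)
    if mate is not None:
        _set_mate(seg, mate, header)
        seg.template_length = tlen
    return seg


def _set_mate(seg, mate, header):
    chrom, pos, strand, unmapped = mate
    if unmapped:
        seg.flag |= 0x8
        seg.next_reference_id = seg.reference_id
        seg.next_reference_start = seg.reference_start
    else:
        seg.next_reference_id = header.get_tid(chrom)
        seg.next_reference_start = pos
        if strand == "-":
            seg.flag |= 0x20


def write_sam(path, segments: Iterable[pysam.AlignedSegment], header: pysam.AlignmentHeader):
    """Write records in input order as headered SAM."""
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            out.write(seg)


def _read_fastq(path) -> list[ReadRecord]:
    reads = []
    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            reads.append(ReadRecord(entry.name, entry.sequence.upper(), entry.quality))
    return reads


def align_fastq(
    bundle: IndexBundle,
    fastq1,
    fastq2=None,
    cfg: MappingConfig | None = None,
    out_sam=None,
    command_line: str = "salt align",
) -> list[pysam.AlignedSegment]:
    """Align a FASTQ file (single- or paired-end) and optionally write SAM."""
    cfg = cfg or MappingConfig()
    header = sam_header(bundle.contigs, command_line)
    slabs = _GraySlabCache(bundle)
    segments: list[pysam.AlignedSegment] = []
    if fastq2 is None:
        for read in _read_fastq(fastq1):
            mr = align_single(read, bundle, cfg, slabs)
            segments.extend(_segments_single(header, mr))
    else:
        reads1 = _read_fastq(fastq1)
        reads2 = _read_fastq(fastq2)
        if len(reads1) != len(reads2):
            raise ValueError("paired FASTQ files differ in read count")
        for r1, r2 in zip(reads1, reads2):
            r1 = ReadRecord(r1.name, r1.seq, r1.quals, 1)
            r2 = ReadRecord(r2.name, r2.seq, r2.quals, 2)
            segments.extend(_segments_pair(header, r1, r2, bundle, cfg, slabs))
    if out_sam is not None:
        write_sam(out_sam, segments, header)
    return segments


def _segments_single(header, mr: MappedRead):
    if not mr.mapped:
        yield _to_segment(header, mr.read, None, 0)
        return
    for i, aln in enumerate(mr.alignments):
        yield _to_segment(header, mr.read, aln, mr.mapq, secondary=i > 0)


def _segments_pair(header, r1, r2, bundle, cfg, slabs):
    mr1 = align_single(r1, bundle, cfg, slabs)
    mr2 = align_single(r2, bundle, cfg, slabs)
    e_max = {1: int(cfg.max_diff_frac * len(r1.seq)), 2: int(cfg.max_diff_frac * len(r2.seq))}
    # rescue an unmapped mate near its anchored partner
    if mr1.mapped and not mr2.mapped:
        rescued = mate_rescue(mr1.primary, r2, cfg.pair, bundle, cfg, slabs)
        if rescued is not None and rescued.edit_distance <= e_max[2]:
            mr2 = MappedRead(r2, [rescued], mr1.mapq)
    elif mr2.mapped and not mr1.mapped:
        rescued = mate_rescue(mr2.primary, r1, cfg.pair, bundle, cfg, slabs)
        if rescued is not None and rescued.edit_distance <= e_max[1]:
            mr1 = MappedRead(r1, [rescued], mr2.mapq)
    pair = pair_hits(mr1, mr2, cfg.pair) if (mr1.mapped and mr2.mapped) else None
    proper = pair is not None
    a1 = pair[0] if pair else mr1.primary
    a2 = pair[1] if pair else mr2.primary
    tlen = 0
    if proper:
        fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
        tlen = rev.end - fwd.pos
    m1 = (a1.chrom, a1.pos, a1.strand, False) if a1 else (None, None, None, True)
    m2 = (a2.chrom, a2.pos, a2.strand, False) if a2 else (None, None, None, True)
    yield _to_segment(
        header, r1, a1, mr1.mapq, paired=True, proper=proper, mate=m2,
        tlen=(tlen if proper and a1.strand == "+" else -tlen if proper else 0),
    )
    yield _to_segment(
        header, r2, a2, mr2.mapq, paired=True, proper=proper, mate=m1,
        tlen=(tlen if proper and a2.strand == "+" else -tlen if proper else 0),
    )
    # secondary ties for each end, unpaired semantics
    for mr, rd, chosen, mmate in ((mr1, r1, a1, m2), (mr2, r2, a2, m1)):
        for aln in mr.alignments:
            if aln is chosen:
                continue
            yield _to_segment(header, rd, aln, 0, secondary=True, paired=True, mate=mmate)
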