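"""Seed sampling and candidate-locus collection.

Seeds are sampled every ``stride_x`` nt along the read (and its reverse
complement) and each is extended to a maximal exact match independently
against the primary-reference index (CFM) and the alternative-reference
index (RFM).  A seed that straddles a known alternative allele is invisible
to the CFM but, as long as it fits inside a SNP window, is found verbatim in
the RFM and projected back to primary coordinates.  Hits vote on diagonals
(hit position minus read offset); nearby diagonals merge into candidate loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .index import CfmIndex, RfmIndex, SaInterval
from .reference_model import revcomp

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class SeedingConfig:
    stride_x: int = 21          # the "-r X" knob: nt between seed starts
    min_seed_len: int = 19
    max_hits_per_seed: int = 512

    def __post_init__(self):
        if self.stride_x < 1:
            raise ValueError("stride_x must be >= 1")
        if self.min_seed_len < 10:
            raise ValueError("min_seed_len must be >= 10")


@dataclass(frozen=True)
class Seed:
    read_offset: int   # 0-based start in the (oriented) read
    length: int
    strand: str        # '+' read as given, '-' its reverse complement
    source: str        # 'CFM' | 'RFM'
    interval: SaInterval


@dataclass
class CandidateLocus:
    chrom: str
    diag_pos: int      # inferred 0-based read-start position on the reference
    strand: str
    support: int = 1
    via_snp: tuple[int, ...] = ()   # RFM window ids, if any seed came through ALT-REF


def _max_exact_extension(idx, seq: str, start: int) -> tuple[int, SaInterval | None]:
    """Longest L with seq[start:start+L] present in the index, plus its interval.

    Exponential probing followed by binary search on the monotone predicate
    "prefix of length L occurs" (a prefix of an occurring string occurs).
    """
    limit = len(seq) - start
    if limit <= 0:
        return 0, None
    if idx.backward_search(seq[start : start + 1]).empty:
        return 0, None
    lo = 1  # known to occur
    step = 1
    while True:
        hi = min(lo + step, limit)
        if idx.backward_search(seq[start : start + hi]).empty:
            hi -= 1
            break
        lo = hi
        if lo == limit:
            hi = limit
            break
        step *= 2
    # binary search in (lo, hi]
    best = lo
    low, high = lo, hi
    while low < high:
        mid = (low + high + 1) // 2
        if idx.backward_search(seq[start : start + mid]).empty:
            high = mid - 1
        else:
            low = mid
    best = low
    return best, idx.backward_search(seq[start : start + best])


def generate_seeds(
    read: str,
    cfm: CfmIndex,
    rfm: RfmIndex | None,
    cfg: SeedingConfig = SeedingConfig(),
) -> list[Seed]:
    """Sample seed starts every stride_x nt on both strands and extend maximally.

    Extension against each index is independent; seeds shorter than
    ``min_seed_len`` or wider than ``max_hits_per_seed`` (repetitive) are
    dropped.  N bases never match (they fall outside both index alphabets),
    so seeds are implicitly split at N.
    """
    read = read.upper()
    if len(read) < cfg.min_seed_len:
        return []
    seeds: list[Seed] = []
    indexes = [("CFM", cfm)] + ([("RFM", rfm)] if rfm is not None else [])
    for strand, seq in ((FORWARD, read), (REVERSE, revcomp(read))):
        for start in range(0, len(seq) - cfg.min_seed_len + 1, cfg.stride_x):
            for source, idx in indexes:
                length, iv = _max_exact_extension(idx, seq, start)
                if length >= cfg.min_seed_len and iv is not None and not iv.empty:
                    if iv.width <= cfg.max_hits_per_seed:
                        seeds.append(Seed(start, length, strand, source, iv))
    return seeds


DIAG_MERGE_TOLERANCE = 8
MAX_CANDIDATE_LOCI = 64


def collect_candidates(
    seeds: Sequence[Seed],
    cfm: CfmIndex,
    rfm: RfmIndex | None,
    merge_tolerance: int = DIAG_MERGE_TOLERANCE,
    max_loci: int = MAX_CANDIDATE_LOCI,
) -> list[CandidateLocus]:
    """Locate seeds, merge hits on nearby diagonals, rank by support.

    Hits on the same strand and contig whose diagonals differ by at most
    ``merge_tolerance`` merge into one locus (support summed, most-voted
    diagonal kept); loci are ordered by support descending then coordinate,
    capped at ``max_loci``.
    """
    hits: list[tuple[str, str, int, int | None]] = []  # (strand, chrom, diag, window)
    for seed in seeds:
        if seed.source == "CFM":
            for chrom, pos in cfm.locate(seed.interval):
                hits.append((seed.strand, chrom, pos - seed.read_offset, None))
        else:
            for chrom, pos, win in rfm.alt_locate(seed.interval):
                hits.append((seed.strand, chrom, pos - seed.read_offset, win))
    hits.sort(key=lambda h: (h[0], h[1], h[2], -1 if h[3] is None else h[3]))
    loci: list[CandidateLocus] = []
    i = 0
    while i < len(hits):
        strand, chrom, diag0, _ = hits[i]
        cluster = [hits[i]]
        j = i + 1
        while (
            j < len(hits)
            and hits[j][0] == strand
            and hits[j][1] == chrom
            and hits[j][2] - cluster[-1][2] <= merge_tolerance
        ):
            cluster.append(hits[j])
            j += 1
        diags = [h[2] for h in cluster]
        # most-voted diagonal, ties to the smallest
        best_diag = max(set(diags), key=lambda d: (diags.count(d), -d))
        wins = tuple(sorted({h[3] for h in cluster if h[3] is not None}))
        loci.append(CandidateLocus(chrom, best_diag, strand, len(cluster), wins))
        i = j
    loci.sort(key=lambda c: (-c.support, c.chrom, c.diag_pos, c.strand))
    return loci[:max_loci]
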