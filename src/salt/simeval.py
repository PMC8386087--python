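"""Synthetic data generation and alignment evaluation.

The simulator emulates a resequencing experiment at desk scale: an i.i.d.
uniform reference genome, a panel of known SNP sites, a donor haplotype that
carries alternative alleles at a fraction of panel sites plus novel
(non-panel) SNPs and short indels, and uniformly sampled reads with
substitution sequencing errors.  Default mutation/error rates are 0.1%
novel SNPs, 0.02% indels, and 0.4% sequencing error.  Every read carries a
truth record (origin contig, 0-based reference coordinate of its leftmost
base, strand) so alignments can be scored.

Evaluation follows the perfect-alignment (PA) convention: on simulated data
a mapped read is a PA when its reported position is within 4 bp of the true
origin; on real data, when its edit distance including clipped bases is
below 10% of the read length.  With N reads, n of them mapped and #PA
perfect, the summary reports Sen = #PA/n x 100 and Acc = n/N x 100 (the
formulas are used verbatim even though "sensitivity" here is a
precision-like quantity).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference_model import BASES, GenomeSequence, SnpPanel, SnpRecord, revcomp


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 100_000
    n_contigs: int = 1
    panel_snp_rate: float = 0.005       # fraction of sites in the SNP panel
    donor_alt_frac: float = 0.5         # panel sites where the donor is ALT
    read_length: int = 100
    n_reads: int = 5_000
    snp_mut_rate: float = 0.001         # novel (non-panel) donor SNPs
    indel_mut_rate: float = 0.0002      # donor indel events, lengths 1-3
    seq_error_rate: float = 0.004       # per-base substitution errors
    seed: int = 1

    def __post_init__(self):
        for r in (self.panel_snp_rate, self.donor_alt_frac, self.snp_mut_rate,
                  self.indel_mut_rate, self.seq_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.read_length > self.genome_length // self.n_contigs:
            raise ValueError("read_length exceeds contig length")


@dataclass(frozen=True)
class TruthRecord:
    name: str
    chrom: str
    pos: int            # 0-based reference coordinate of the leftmost base
    strand: str
    n_errors: int = 0   # sequencing errors injected into this read


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: list[GenomeSequence]
    panel: SnpPanel
    donor: dict[str, str]
    reads: list[tuple[str, str]]        # (name, sequence)
    truth: list[TruthRecord]
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def truth_by_name(self) -> dict[str, TruthRecord]:
        return {t.name: t for t in self.truth}


_ALT_COUNT_PROBS = (0.90, 0.08, 0.02)   # 1, 2 or 3 alternative alleles


def simulate(cfg: SimulationConfig, out_dir=None) -> SimulatedDataset:
    """Generate reference, panel, donor, reads, and truth; optionally write files.

    Output is bit-reproducible for a fixed config (one RNG stream with a
    fixed draw order: genome, panel, donor per contig, then reads).  Files
    written when ``out_dir`` is given: ``ref.fasta``, ``panel.tsv``,
    ``reads.fastq``, ``truth.tsv``.
    """
    rng = np.random.default_rng(cfg.seed)
    per_contig = cfg.genome_length // cfg.n_contigs
    contigs = []
    for ci in range(cfg.n_contigs):
        bases = rng.integers(0, 4, per_contig)
        seq = "".join(BASES[b] for b in bases)
        contigs.append(GenomeSequence(f"chr{ci + 1}", seq))

    panel_records = []
    for g in contigs:
        site_mask = rng.random(g.length) < cfg.panel_snp_rate
        for pos in np.nonzero(site_mask)[0]:
            ref_b = g.seq[pos]
            n_alt = 1 + int(np.searchsorted(np.cumsum(_ALT_COUNT_PROBS), rng.random()))
            others = [b for b in BASES if b != ref_b]
            alts = tuple(sorted(rng.choice(others, size=min(n_alt, 3), replace=False)))
            panel_records.append(
                SnpRecord(g.name, int(pos), ref_b, alts, f"snp{len(panel_records):06d}")
            )
    panel = SnpPanel(panel_records)

    donor: dict[str, str] = {}
    donor_map: dict[str, np.ndarray] = {}   # donor index -> reference coordinate
    for g in contigs:
        contig_sites = panel.in_range(g.name, 0, g.length)
        alt_site: dict[int, str] = {}
        take = rng.random(len(contig_sites)) < cfg.donor_alt_frac
        for rec, t in zip(contig_sites, take):
            if t:
                alt_site[rec.pos] = str(rng.choice(rec.alt_alleles))
        n = g.length
        indel_ev = rng.random(n) < cfg.indel_mut_rate
        is_ins = rng.random(n) < 0.5
        ind_len = rng.integers(1, 4, n)
        novel_ev = rng.random(n) < cfg.snp_mut_rate
        novel_shift = rng.integers(1, 4, n)
        dseq: list[str] = []
        d2r: list[int] = []
        i = 0
        while i < n:
            if indel_ev[i]:
                if is_ins[i]:
                    for b in rng.integers(0, 4, int(ind_len[i])):
                        dseq.append(BASES[b])
                        d2r.append(i)
                else:
                    i += int(ind_len[i])
                    continue
            base = g.seq[i]
            if i in alt_site:
                base = alt_site[i]
            elif novel_ev[i]:
                base = BASES[(BASES.index(base) + int(novel_shift[i])) % 4]
            dseq.append(base)
            d2r.append(i)
            i += 1
        donor[g.name] = "".join(dseq)
        donor_map[g.name] = np.asarray(d2r, dtype=np.int64)

    names = [g.name for g in contigs]
    dlens = np.array([len(donor[nm]) for nm in names], dtype=np.float64)
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    L = cfg.read_length
    for ri in range(cfg.n_reads):
        ci = int(rng.choice(len(names), p=dlens / dlens.sum())) if len(names) > 1 else 0
        dn = donor[names[ci]]
        start = int(rng.integers(0, len(dn) - L + 1))
        frag = dn[start : start + L]
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            frag = revcomp(frag)
        err = rng.random(L) < cfg.seq_error_rate
        shifts = rng.integers(1, 4, L)
        if err.any():
            chars = list(frag)
            for p in np.nonzero(err)[0]:
                chars[p] = BASES[(BASES.index(chars[p]) + int(shifts[p])) % 4]
            frag = "".join(chars)
        name = f"sim_{ri:06d}"
        reads.append((name, frag))
        truth.append(
            TruthRecord(name, names[ci], int(donor_map[names[ci]][start]), strand, int(err.sum()))
        )

    ds = SimulatedDataset(cfg, contigs, panel, donor, reads, truth)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SimulatedDataset, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_path = out_dir / "ref.fasta"
    SeqIO.write(
        [SeqRecord(Seq(g.seq), id=g.name, description="") for g in ds.reference],
        str(ref_path), "fasta",
    )
    panel_path = out_dir / "panel.tsv"
    with open(panel_path, "w") as fh:
        for r in ds.panel:
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.ref_allele}\t{','.join(r.alt_alleles)}\t{r.snp_id}\n")
    fq_path = out_dir / "reads.fastq"
    with open(fq_path, "w") as fh:
        for name, seq in ds.reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("name\tchrom\tpos\tstrand\tn_errors\n")
        for t in ds.truth:
            fh.write(f"{t.name}\t{t.chrom}\t{t.pos}\t{t.strand}\t{t.n_errors}\n")
    ds.paths = {"ref": ref_path, "panel": panel_path, "reads": fq_path, "truth": truth_path}


def load_truth(path) -> dict[str, TruthRecord]:
    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            t = TruthRecord(
                row["name"], row["chrom"], int(row["pos"]), row["strand"],
                int(row.get("n_errors", 0) or 0),
            )
            out[t.name] = t
    return out


@dataclass
class EvaluationSummary:
    N: int              # total reads
    n: int              # mapped reads
    n_pa: int           # perfect alignments
    sen: float          # #PA / n x 100 (0 when nothing mapped)
    acc: float          # n / N x 100
    uniq: float         # percentage with MAPQ > 0
    unmapped: int


PA_DISTANCE = 4         # simulated mode: within 4 bp of the true origin
PA_EDIT_FRAC = 0.10     # real mode: edit distance incl. clipping below 10%


def evaluate(sam, truth=None, mode: str = "simulated", ref=None, panel=None) -> EvaluationSummary:
    """Score a SAM file against the truth table (or the 10% edit rule).

    ``truth`` is a path or a name->TruthRecord dict; required in simulated
    mode, where an aligned name absent from it is an error.  Only primary
    records count; a read is mapped if its primary record is mapped.  In
    real mode edit distances are taken from the NM tag plus clipped bases,
    so ``ref``/``panel`` are accepted for interface symmetry but not needed
    for SAM produced by this package.
    """
    if mode not in ("simulated", "real"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "simulated":
        if truth is None:
            raise ValueError("simulated mode requires a truth table")
        if not isinstance(truth, dict):
            truth = load_truth(truth)
    N = n = n_pa = uniq = 0
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            N += 1
            if rec.is_unmapped:
                continue
            n += 1
            if rec.mapping_quality > 0:
                uniq += 1
            if mode == "simulated":
                t = truth.get(rec.query_name)
                if t is None:
                    raise ValueError(f"read {rec.query_name!r} missing from truth table")
                if rec.reference_name == t.chrom and abs(rec.reference_start - t.pos) <= PA_DISTANCE:
                    n_pa += 1
            else:
                L = rec.query_length or len(rec.query_sequence or "")
                clipped = sum(c for op, c in (rec.cigartuples or ()) if op in (4, 5))
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                if L and (nm + clipped) < PA_EDIT_FRAC * L:
                    n_pa += 1
    sen = (n_pa / n * 100.0) if n else 0.0
    acc = (n / N * 100.0) if N else 0.0
    uniq_pct = (uniq / N * 100.0) if N else 0.0
    return EvaluationSummary(N, n, n_pa, sen, acc, uniq_pct, N - n)
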