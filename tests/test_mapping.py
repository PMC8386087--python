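import pysam
import pytest

from salt.index import IndexBundle
from salt.mapping import (
    MappingConfig,
    PairConstraint,
    ReadRecord,
    align_fastq,
    align_single,
    compute_mapq,
    mate_rescue,
    pair_hits,
    sam_header,
    write_sam,
)
from salt.reference_model import GenomeSequence, SnpPanel, revcomp
from salt.seeding import SeedingConfig

from conftest import apply_alts


CFG = MappingConfig(seeding=SeedingConfig(stride_x=10, min_seed_len=12))


class TestAlignSingle:
    def test_error_free_read_maps_exactly(self, toy_bundle):
        read = ReadRecord("r1", toy_bundle.contigs[0].seq[150:250])
        mr = align_single(read, toy_bundle, CFG)
        assert mr.mapped
        aln = mr.primary
        assert (aln.chrom, aln.pos, aln.strand, aln.edit_distance) == ("c1", 150, "+", 0)
        assert aln.cigar == [("M", 100)]
        assert mr.mapq == 60

    def test_reverse_strand_read(self, toy_bundle):
        read = ReadRecord("r1", revcomp(toy_bundle.contigs[0].seq[150:250]))
        mr = align_single(read, toy_bundle, CFG)
        assert (mr.primary.pos, mr.primary.strand) == (150, "-")

    def test_two_copy_repeat_yields_deterministic_ties(self):
        unit = "ACGTTGCAACGGATTCTAGCAGGCATCGTACA"
        pad1, pad2 = "TTTTTTTTTT", "GGGGGGGGGG"
        g = GenomeSequence("c1", pad1 + unit + pad2 + unit + pad1)
        bundle = IndexBundle([g], SnpPanel([]), k=21)
        mr = align_single(ReadRecord("r", unit), bundle, CFG)
        assert len(mr.alignments) == 2
        assert [a.pos for a in mr.alignments] == [10, 52]
        assert mr.mapq == 0

    def test_excessive_mismatches_unmapped(self, toy_bundle):
        seq = list(toy_bundle.contigs[0].seq[150:250])
        for i in range(0, 100, 7):  # ~15% scattered mismatches
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        mr = align_single(ReadRecord("r", "".join(seq)), toy_bundle, CFG)
        assert not mr.mapped

    def test_donor_alt_alleles_align_with_nm_zero(self, toy_bundle, toy_panel):
        donor = apply_alts(toy_bundle.contigs[0], toy_panel, [120, 121])
        mr = align_single(ReadRecord("r", donor[100:180]), toy_bundle, CFG)
        aln = mr.primary
        assert (aln.pos, aln.edit_distance) == (100, 0)
        assert set(aln.snp_ids_used) == {"s1", "s2"}

    def test_overlong_read_rejected(self, toy_bundle):
        with pytest.raises(ValueError, match="short-read scope"):
            align_single(ReadRecord("r", "A" * 10_001), toy_bundle, CFG)


class TestPairing:
    def test_insert_window_arithmetic(self):
        pc = PairConstraint(u=400, sigma=50)
        assert (pc.min_distance, pc.max_distance) == (250, 550)

    def _mapped(self, bundle, pos, strand, L=50):
        seq = bundle.contigs[0].seq[pos : pos + L]
        read = ReadRecord("r", seq if strand == "+" else revcomp(seq))
        return align_single(read, bundle, CFG)

    def test_fr_pair_within_window_accepted(self, toy_bundle):
        pc = PairConstraint(u=200, sigma=30)
        h1 = self._mapped(toy_bundle, 50, "+")
        h2 = self._mapped(toy_bundle, 200, "-")
        pair = pair_hits(h1, h2, pc)
        assert pair is not None
        assert (pair[0].pos, pair[1].pos) == (50, 200)

    def test_ff_orientation_rejected(self, toy_bundle):
        pc = PairConstraint(u=200, sigma=30)
        h1 = self._mapped(toy_bundle, 50, "+")
        h2 = self._mapped(toy_bundle, 200, "+")
        assert pair_hits(h1, h2, pc) is None

    def test_distance_outside_window_rejected(self, toy_bundle):
        pc = PairConstraint(u=200, sigma=10)
        h1 = self._mapped(toy_bundle, 10, "+")
        h2 = self._mapped(toy_bundle, 320, "-")
        assert pair_hits(h1, h2, pc) is None


class TestMateRescue:
    def test_mate_in_window_rescued(self, toy_bundle):
        pc = PairConstraint(u=150, sigma=20)
        anchor = align_single(
            ReadRecord("r/1", toy_bundle.contigs[0].seq[50:100]), toy_bundle, CFG
        ).primary
        mate_seq = revcomp(toy_bundle.contigs[0].seq[160:200])
        rescued = mate_rescue(anchor, ReadRecord("r/2", mate_seq), pc, toy_bundle, CFG)
        assert rescued is not None
        assert (rescued.pos, rescued.strand, rescued.edit_distance) == (160, "-", 0)

    def test_no_hit_above_threshold(self, toy_bundle):
        pc = PairConstraint(u=150, sigma=20)
        anchor = align_single(
            ReadRecord("r/1", toy_bundle.contigs[0].seq[50:100]), toy_bundle, CFG
        ).primary
        rescued = mate_rescue(anchor, ReadRecord("r/2", "ACGT" * 10), pc, toy_bundle, CFG)
        assert rescued is None

    def test_wrong_orientation_not_rescued(self, toy_bundle):
        # mate present forward where a reverse mate is expected: window SW on
        # the reverse complement must not reach the score threshold
        pc = PairConstraint(u=150, sigma=20)
        anchor = align_single(
            ReadRecord("r/1", toy_bundle.contigs[0].seq[50:100]), toy_bundle, CFG
        ).primary
        mate_seq = toy_bundle.contigs[0].seq[160:200]  # forward orientation
        rescued = mate_rescue(anchor, ReadRecord("r/2", mate_seq), pc, toy_bundle, CFG)
        assert rescued is None


class TestMapq:
    @pytest.mark.parametrize(
        "best,second,ties,expect",
        [(0, None, 2, 0), (0, None, 1, 60), (0, -3, 1, 18), (0, -20, 1, 60)],
    )
    def test_formula(self, best, second, ties, expect):
        assert compute_mapq(best, second, ties) == expect


class TestSamOutput:
    def test_header_only_file(self, toy_bundle, tmp_path):
        path = tmp_path / "empty.sam"
        write_sam(path, [], sam_header(toy_bundle.contigs))
        with pysam.AlignmentFile(str(path)) as fh:
            assert fh.header.nreferences == 1
            assert list(fh) == []

    def test_unmapped_read_flag(self, toy_bundle, tmp_path):
        fq = tmp_path / "r.fq"
        fq.write_text("@u1\n" + "ACGT" * 10 + "\n+\n" + "I" * 40 + "\n")
        out = tmp_path / "o.sam"
        align_fastq(toy_bundle, fq, cfg=CFG, out_sam=out)
        with pysam.AlignmentFile(str(out)) as fh:
            (rec,) = list(fh)
        assert rec.is_unmapped and rec.flag & 0x4

    def test_proper_pair_flag_pattern(self, toy_bundle, tmp_path):
        seq = toy_bundle.contigs[0].seq
        r1 = seq[50:100]
        r2 = revcomp(seq[200:250])
        (tmp_path / "r1.fq").write_text(f"@p1\n{r1}\n+\n{'I' * 50}\n")
        (tmp_path / "r2.fq").write_text(f"@p1\n{r2}\n+\n{'I' * 50}\n")
        out = tmp_path / "o.sam"
        cfg = MappingConfig(seeding=CFG.seeding, pair=PairConstraint(u=200, sigma=30))
        align_fastq(toy_bundle, tmp_path / "r1.fq", tmp_path / "r2.fq", cfg, out_sam=out)
        with pysam.AlignmentFile(str(out)) as fh:
            recs = [r for r in fh if not r.is_secondary]
        assert [r.flag for r in recs] == [99, 147]
        assert recs[0].template_length == 200
        assert recs[1].template_length == -200

    def test_reverse_read_stored_as_aligned(self, toy_bundle, tmp_path):
        seq = revcomp(toy_bundle.contigs[0].seq[150:250])
        fq = tmp_path / "r.fq"
        fq.write_text(f"@m1\n{seq}\n+\n{'I' * 100}\n")
        out = tmp_path / "o.sam"
        align_fastq(toy_bundle, fq, cfg=CFG, out_sam=out)
        with pysam.AlignmentFile(str(out)) as fh:
            (rec,) = [r for r in fh if not r.is_secondary]
        assert rec.is_reverse
        assert rec.query_sequence == toy_bundle.contigs[0].seq[150:250]
        assert rec.get_tag("NM") == 0
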