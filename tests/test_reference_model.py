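import itertools

import numpy as np
import pytest

from salt.reference_model import (
    GenomeSequence,
    SnpPanel,
    SnpRecord,
    build_alt_reference,
    encode_gray,
    encode_read_gray,
    load_fasta,
    load_snp_panel,
    mask_to_bits,
    revcomp,
)

from conftest import make_genome, make_panel


class TestLoadFasta:
    def test_case_normalised_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nacgt\n")
        (g,) = load_fasta(p)
        assert (g.name, g.seq, g.length) == ("c1", "ACGT", 4)

    def test_multi_contig_file_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">b\nAC\n>a\nGT\n")
        gs = load_fasta(p)
        assert [g.name for g in gs] == ["b", "a"]

    def test_invalid_character_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACXT\n")
        with pytest.raises(ValueError, match="invalid character"):
            load_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            load_fasta(p)


class TestLoadPanel:
    def _ref(self):
        return [GenomeSequence("c1", "AACGT")]

    def test_coordinates_become_zero_based(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("c1\t3\tC\tT\trs1\n")
        panel = load_snp_panel(p, self._ref())
        (rec,) = panel
        assert (rec.pos, rec.ref_allele, rec.alt_alleles) == (2, "C", ("T",))

    def test_ref_mismatch_dropped_and_indel_skipped(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("c1\t3\tG\tT\trs1\nc1\t2\tAC\tA\trs2\nc1\t4\tG\tA,C\trs3\n")
        panel = load_snp_panel(p, self._ref())
        assert [r.snp_id for r in panel] == ["rs3"]
        assert panel.records[0].alt_alleles == ("A", "C")

    def test_unknown_contig_is_error(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("c9\t1\tA\tC\trs1\n")
        with pytest.raises(ValueError, match="unknown contig"):
            load_snp_panel(p, self._ref())

    def test_vcf_dialect(self, tmp_path):
        p = tmp_path / "panel.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=5>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c1\t3\trs1\tC\tT\t.\t.\t.\n"
            "c1\t4\trs2\tG\tGA\t.\t.\t.\n"
        )
        panel = load_snp_panel(p, self._ref())
        assert [(r.pos, r.alt_alleles) for r in panel] == [(2, ("T",))]


class TestGrayEncoding:
    def test_snp_site_mask_is_allele_union(self):
        g = GenomeSequence("c1", "G")
        panel = SnpPanel([SnpRecord("c1", 0, "G", ("T",), "s")])
        assert mask_to_bits(encode_gray(g, panel)[0]) == "0011"

    def test_non_snp_site_one_hot(self):
        g = GenomeSequence("c1", "ACGTN")
        masks = encode_gray(g, SnpPanel([]))
        assert list(masks) == [0b1000, 0b0100, 0b0010, 0b0001, 0b0000]

    def test_all_alleles_site(self):
        g = GenomeSequence("c1", "A")
        panel = SnpPanel([SnpRecord("c1", 0, "A", ("C", "G", "T"), "s")])
        assert encode_gray(g, panel)[0] == 0b1111

    def test_popcount_distinguishes_panel_sites(self, toy_genome, toy_panel):
        masks = encode_gray(toy_genome, toy_panel)
        pop = np.array([bin(m).count("1") for m in masks])
        panel_pos = {r.pos for r in toy_panel}
        for i in range(toy_genome.length):
            assert (pop[i] >= 2) == (i in panel_pos)

    @pytest.mark.parametrize(
        "read,expect",
        [("GT", [0b0010, 0b0001]), ("N", [0b0000]), ("", [])],
    )
    def test_read_encoding(self, read, expect):
        assert list(encode_read_gray(read)) == expect


class TestAltReference:
    def test_worked_single_snp_window(self):
        g = GenomeSequence("c1", "AAAAACAAAAA")
        panel = SnpPanel([SnpRecord("c1", 5, "C", ("G",), "s0")])
        alt = build_alt_reference([g], panel, k=2)
        assert alt.text == "AAGAA#"
        a = alt.anchors[0]
        assert (a.chrom, a.start, a.length, a.snp_ids) == ("c1", 3, 5, ("s0",))

    def test_nearby_snps_enumerate_combinations_minus_all_ref(self):
        g = GenomeSequence("c1", "AAACAGAAA")
        panel = SnpPanel(
            [
                SnpRecord("c1", 3, "C", ("T",), "s0"),
                SnpRecord("c1", 5, "G", ("A",), "s1"),
            ]
        )
        alt = build_alt_reference([g], panel, k=3)
        got = {alt.window_text(i) for i in range(alt.n_windows)}
        # brute-force enumeration over both windows, dropping all-ref haplotypes
        expect = set()
        for centre in (3, 5):
            start, end = centre - 3, centre + 4
            for c3, c5 in itertools.product("CT", "GA"):
                hap = list(g.seq[start:end])
                hap[3 - start] = c3
                hap[5 - start] = c5
                if (c3, c5) != ("C", "G"):
                    expect.add("".join(hap))
        assert got == expect

    def test_windows_skip_n_and_clip_at_ends(self):
        g = GenomeSequence("c1", "CANAAAAT")
        panel = SnpPanel(
            [
                SnpRecord("c1", 0, "C", ("G",), "near_n"),  # window holds the N
                SnpRecord("c1", 7, "T", ("A",), "at_end"),
            ]
        )
        alt = build_alt_reference([g], panel, k=3)
        assert [a.snp_ids for a in alt.anchors] == [("at_end",)]
        assert alt.window_text(0) == "AAAA"  # clipped at the contig end

    def test_every_window_differs_only_by_panel_alts(self, toy_genome, toy_panel):
        alt = build_alt_reference([toy_genome], toy_panel, k=9)
        assert alt.text.endswith("#")
        assert alt.text.count("#") == alt.n_windows
        for i, a in enumerate(alt.anchors):
            win = alt.window_text(i)
            primary = toy_genome.seq[a.start : a.start + a.length]
            diffs = [x for x in range(len(win)) if win[x] != primary[x]]
            assert diffs, "window identical to primary reference"
            for x in diffs:
                rec = toy_panel.get(a.chrom, a.start + x)
                assert rec is not None and win[x] in rec.alt_alleles

    def test_donor_substrings_covered(self):
        # every short donor substring containing an alt allele occurs in ALT-REF
        g = make_genome(200, seed=3)
        panel = make_panel(g, [40, 44, 120], seed=4)
        alt = build_alt_reference([g], panel, k=7)
        donor = list(g.seq)
        for r in panel:
            donor[r.pos] = r.alt_alleles[0]
        donor = "".join(donor)
        k = 7
        for r in panel:
            for s in range(max(0, r.pos - k), r.pos + 1):
                e = min(len(donor), s + k + 1)
                if e - s < 3:
                    continue
                sub = donor[s:e]
                if sub == g.seq[s:e]:
                    continue
                assert sub in alt.text, (r.snp_id, sub)


def test_revcomp_involution():
    s = "ACGTNNTGCA"
    assert revcomp(revcomp(s)) == s
    assert revcomp("ACGT") == "ACGT"


def test_panel_rejects_duplicates_and_bad_alleles():
    with pytest.raises(ValueError):
        SnpRecord("c1", 0, "A", ("A",), "x")
    with pytest.raises(ValueError):
        SnpPanel(
            [
                SnpRecord("c1", 5, "A", ("C",), "a"),
                SnpRecord("c1", 5, "A", ("G",), "b"),
            ]
        )
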