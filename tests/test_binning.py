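"""Binning, RPKM and coordinate conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from terseq.binning import (Bin, OperonAnnotation, attach_sequences,
                            bin_counts_from_intervals, bin_genomic_interval,
                            counts_to_rpkm, partition_operon,
                            read_operons_bed, read_operons_gff3,
                            reads_from_sam, transcript_to_genomic)


@pytest.fixture
def minus_operon():
    return OperonAnnotation(name="opM", chrom="chr", start=1000, end=3699,
                            strand="-")


class TestPartition:
    def test_2700_nt_operon_has_the_documented_bins(self):
        bins = partition_operon(2700)
        assert len(bins) == 9
        assert (bins[0].start, bins[0].end) == (1, 300)
        assert (bins[4].start, bins[4].end) == (1201, 1500)
        assert (bins[8].start, bins[8].end) == (2401, 2700)
        assert bins[8].midpoint == 2550.0

    def test_last_bin_truncated(self):
        bins = partition_operon(650)
        assert [(b.start, b.end) for b in bins] == [(1, 300), (301, 600),
                                                    (601, 650)]
        assert bins[-1].length == 50

    def test_short_operon_single_bin_with_warning(self):
        with pytest.warns(UserWarning):
            bins = partition_operon(120)
        assert len(bins) == 1 and bins[0].length == 120

    def test_bins_abut_and_cover(self):
        bins = partition_operon(3001)
        assert bins[0].start == 1
        for a, b in zip(bins, bins[1:]):
            assert b.start == a.end + 1
        assert bins[-1].end == 3001

    def test_minus_strand_bin0_maps_to_3prime_genomic_end(self, minus_operon):
        bins = partition_operon(minus_operon)
        assert bin_genomic_interval(minus_operon, bins[0]) == (3400, 3699)

    def test_transcript_genomic_round_trip_both_strands(self):
        plus = OperonAnnotation(name="p", chrom="c", start=501, end=1500,
                                strand="+")
        minus = OperonAnnotation(name="m", chrom="c", start=501, end=1500,
                                 strand="-")
        for t in (1, 300, 777, 1000):
            assert transcript_to_genomic(plus, t) == 500 + t
            assert transcript_to_genomic(minus, t) == 1501 - t
        # inverse: genomic -> transcript -> genomic
        for ann in (plus, minus):
            for t in (1, 500, 1000):
                g = transcript_to_genomic(ann, t)
                back = (g - ann.start + 1 if ann.strand == "+"
                        else ann.end - g + 1)
                assert back == t


class TestRpkm:
    @pytest.mark.parametrize("count,lib,length,expected", [
        (10, 1e6, 300, 10_000 / 300),
        (0, 3e6, 500, 0.0),
        (300, 5e6, 300, 200.0),
    ])
    def test_formula(self, count, lib, length, expected):
        assert counts_to_rpkm(count, lib, length) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            counts_to_rpkm(-1, 1e6, 300)
        with pytest.raises(ValueError):
            counts_to_rpkm(1, 0, 300)
        with pytest.raises(ValueError):
            counts_to_rpkm(1, 1e6, 0)

    @given(st.integers(0, 10**6), st.integers(1, 10**8), st.integers(1, 10**5),
           st.integers(2, 5))
    @settings(max_examples=50, deadline=None)
    def test_linearity_and_scaling(self, count, lib, length, c):
        base = counts_to_rpkm(count, lib, length)
        assert counts_to_rpkm(c * count, lib, length) == pytest.approx(c * base)
        assert counts_to_rpkm(count, c * lib, length) == pytest.approx(base / c)
        assert counts_to_rpkm(count, lib, c * length) == pytest.approx(base / c)


class TestBinCounts:
    plus = OperonAnnotation(name="op", chrom="chr", start=1001, end=4000,
                            strand="+")

    def bins(self):
        return partition_operon(self.plus)

    def test_read_inside_one_bin(self):
        reads = [("chr", 1650, 1700)]  # transcript 650-700, bin 2
        counts, ignored = bin_counts_from_intervals(reads, self.bins(),
                                                    self.plus)
        assert counts.tolist() == [0, 0, 1, 0, 0, 0, 0, 0, 0, 0]
        assert ignored == 0

    def test_straddling_read_counted_once_by_5prime_base(self):
        # 5' base at transcript 590 (bin 1), read extends into bin 2
        reads = [("chr", 1590, 1650)]
        counts, _ = bin_counts_from_intervals(reads, self.bins(), self.plus)
        assert counts.sum() == 1 and counts[1] == 1

    def test_minus_strand_uses_genomic_end_as_5prime(self, minus_operon):
        bins = partition_operon(minus_operon)
        # genomic end 3650 -> transcript 3699-3650+1 = 50 -> bin 0
        counts, _ = bin_counts_from_intervals([("chr", 3600, 3650)], bins,
                                              minus_operon)
        assert counts[0] == 1 and counts.sum() == 1

    def test_wrong_chromosome_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="ignored"):
            counts, ignored = bin_counts_from_intervals(
                [("other", 1650, 1700)], self.bins(), self.plus)
        assert ignored == 1 and counts.sum() == 0

    def test_total_counts_equal_assigned_reads(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(1001, 4001, size=500)
        reads = [("chr", int(s), int(min(s + 49, 4000))) for s in starts]
        counts, ignored = bin_counts_from_intervals(reads, self.bins(),
                                                    self.plus)
        assert counts.sum() + ignored == 500

    def test_uniform_reads_within_multinomial_envelope(self):
        n, n_bins = 1000, 10
        ann = OperonAnnotation(name="u", chrom="chr", start=1, end=3000,
                               strand="+")
        bins = partition_operon(ann)
        rng = np.random.default_rng(11)
        pos = rng.integers(1, 3001, size=n)
        reads = [("chr", int(p), int(p)) for p in pos]
        counts, _ = bin_counts_from_intervals(reads, bins, ann)
        lo = binom.ppf(0.005, n, 1 / n_bins)
        hi = binom.ppf(0.995, n, 1 / n_bins)
        assert np.all(counts >= lo) and np.all(counts <= hi)


class TestAnnotationIO:
    def test_bed_round_trip_coordinates(self, tmp_path):
        bed = tmp_path / "ops.bed"
        bed.write_text("chr\t999\t3699\topA\t0\t+\n"
                       "chr\t99\t1099\topB\t0\t-\n")
        ops = read_operons_bed(bed)
        assert ops[0].start == 1000 and ops[0].end == 3699
        assert ops[0].length == 2700
        assert ops[1].strand == "-" and ops[1].length == 1000

    def test_gff3_native_coordinates(self, tmp_path):
        gff = tmp_path / "ops.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr\ttest\toperon\t1000\t3699\t.\t+\t.\tID=opA;Name=opA\n")
        ops = read_operons_gff3(gff)
        assert ops[0].name == "opA"
        assert ops[0].start == 1000 and ops[0].end == 3699

    def test_attach_sequences_reverse_complements_minus_strand(self, tmp_path):
        fa = tmp_path / "genome.fa"
        fa.write_text(">chr\n" + "ACGTACGTAA" + "\n")
        plus = OperonAnnotation(name="p", chrom="chr", start=1, end=4,
                                strand="+")
        minus = OperonAnnotation(name="m", chrom="chr", start=1, end=4,
                                 strand="-")
        attach_sequences([plus, minus], fa)
        assert plus.sequence == "ACGT"
        assert minus.sequence == "ACGT"[::-1].translate(
            str.maketrans("ACGT", "TGCA"))

    def test_sam_reads_extracted_one_based(self, tmp_path):
        import pysam

        sam = tmp_path / "reads.sam"
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"LN": 5000, "SN": "chr"}]}
        with pysam.AlignmentFile(sam, "w", header=header) as fh:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = "r1"
            a.query_sequence = "A" * 50
            a.reference_id = 0
            a.reference_start = 1649  # 0-based -> 1-based 1650
            a.cigarstring = "50M"
            a.flag = 0
            a.mapping_quality = 60
            fh.write(a)
        reads = reads_from_sam(sam, "chr")
        assert reads == [("chr", 1650, 1699)]


class TestValidation:
    def test_annotation_invariants(self):
        with pytest.raises(ValueError):
            OperonAnnotation(name="x", chrom="c", start=10, end=5, strand="+")
        with pytest.raises(ValueError):
            OperonAnnotation(name="x", chrom="c", start=1, end=10, strand="*")
        with pytest.raises(ValueError):
            OperonAnnotation(name="x", chrom="c", start=1, end=10, strand="+",
                             sequence="ACGT")
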