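"""Transcript models, annotation parsing, coordinate collapsing, and
gene- vs transcript-level uniqueness."""

import numpy as np
import pytest

from minuniq.genome_index import build_index
from minuniq.mul_core import compute_mul_array
from minuniq.transcriptome import (
    CollapsedAlignment,
    TranscriptModel,
    build_combined_index,
    classify_read,
    compute_transcript_mul,
    count_overlaps,
    extract_spliced_sequence,
    parse_annotation,
    transcript_to_genomic,
    write_bed12,
    write_refflat,
)
from conftest import random_genome


@pytest.fixture
def two_exon():
    return TranscriptModel("T1", "G1", "chr1", "+", ((10, 13), (16, 19)))


class TestModelInvariants:
    @pytest.mark.parametrize(
        "exons", [(), ((5, 5),), ((10, 5),), ((10, 20), (15, 25)), ((16, 19), (10, 13))]
    )
    def test_bad_exons_rejected(self, exons):
        with pytest.raises(ValueError):
            TranscriptModel("T", "G", "chr1", "+", exons)

    def test_spliced_length(self, two_exon):
        assert two_exon.spliced_length == 6


class TestParsing:
    def test_bed12_blocks(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t10\t19\ttx1\t0\t+\t10\t19\t0\t2\t3,3,\t0,6,\n")
        (model,) = parse_annotation(bed, format="BED12")
        assert model.exons == ((10, 13), (16, 19))
        assert model.spliced_length == 6

    def test_refflat_single_exon(self, tmp_path):
        rf = tmp_path / "t.refFlat"
        rf.write_text("G1\tT1\tchr2\t-\t100\t200\t100\t200\t1\t100,\t200,\n")
        (model,) = parse_annotation(rf, format="refFlat")
        assert model.exons == ((100, 200),) and model.strand == "-"

    def test_exon_count_mismatch_has_line_number(self, tmp_path):
        rf = tmp_path / "t.refFlat"
        rf.write_text("G1\tT1\tchr1\t+\t0\t10\t0\t10\t2\t0,\t10,\n")
        with pytest.raises(ValueError, match=":1:"):
            parse_annotation(rf, format="refFlat")

    def test_unsorted_blocks_rejected(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t10\t30\ttx\t0\t+\t10\t30\t0\t2\t3,3,\t10,0,\n")
        with pytest.raises(ValueError):
            parse_annotation(bed, format="BED12")

    def test_writers_roundtrip(self, tmp_path, two_exon):
        other = TranscriptModel("T2", "G1", "chr1", "-", ((5, 8), (12, 30)))
        for writer, fmt, name in (
            (write_refflat, "refFlat", "a.refFlat"),
            (write_bed12, "BED12", "a.bed"),
        ):
            writer([two_exon, other], tmp_path / name)
            back = parse_annotation(tmp_path / name, format=fmt)
            assert [(t.transcript_id, t.chrom, t.strand, t.exons) for t in back] == [
                (t.transcript_id, t.chrom, t.strand, t.exons)
                for t in (two_exon, other)
            ]


class TestSplicedSequence:
    def test_junction_concatenation(self):
        genome = {"chrA": "AAACCCGGGTTT"}
        t = TranscriptModel("T", "G", "chrA", "+", ((0, 3), (9, 12)))
        assert extract_spliced_sequence(genome, t) == "AAATTT"

    def test_minus_strand_revcomp(self):
        genome = {"chrA": "AAACCCGGGTTT"}
        t = TranscriptModel("T", "G", "chrA", "-", ((0, 3),))
        assert extract_spliced_sequence(genome, t) == "TTT"

    def test_out_of_bounds_exon(self):
        t = TranscriptModel("T", "G", "chrA", "+", ((0, 50),))
        with pytest.raises(ValueError, match="outside"):
            extract_spliced_sequence({"chrA": "ACGT"}, t)


class TestCoordinateCollapse:
    def test_junction_spanning(self, two_exon):
        a = transcript_to_genomic(two_exon, 2, 2)
        assert (a.genomic_start, a.genomic_end) == (12, 17)

    def test_first_base(self, two_exon):
        a = transcript_to_genomic(two_exon, 0, 1)
        assert (a.genomic_start, a.genomic_end) == (10, 11)

    def test_minus_strand_first_base_maps_rightmost(self):
        t = TranscriptModel("T1", "G1", "chr1", "-", ((10, 13), (16, 19)))
        a = transcript_to_genomic(t, 0, 1)
        assert (a.genomic_start, a.genomic_end) == (18, 19)

    def test_out_of_range(self, two_exon):
        with pytest.raises(IndexError):
            transcript_to_genomic(two_exon, 5, 2)


class TestClassify:
    def test_identical_coordinates_across_isoforms(self):
        # the two transcript-level rules genuinely diverge here
        aln = [
            CollapsedAlignment("c", 100, 125, "T1"),
            CollapsedAlignment("c", 100, 125, "T2"),
            CollapsedAlignment("c", 100, 125, "genome"),
        ]
        assert classify_read(aln, "coordinate") == "transcript_unique"
        assert classify_read(aln, "single_source") == "gene_unique"

    def test_two_loci_multimapping(self):
        aln = [CollapsedAlignment("c", 100, 125, "T1"), CollapsedAlignment("c", 300, 325, "T3")]
        assert classify_read(aln) == "multimapping"

    def test_shared_start_is_gene_unique(self):
        aln = [CollapsedAlignment("c", 100, 125, "T1"), CollapsedAlignment("c", 100, 140, "T2")]
        assert classify_read(aln) == "gene_unique"

    def test_same_position_other_chromosome_multimaps(self):
        aln = [CollapsedAlignment("c1", 100, 125), CollapsedAlignment("c2", 100, 125)]
        assert classify_read(aln) == "multimapping"

    def test_empty_unmapped(self):
        assert classify_read([]) == "unmapped"


def _tx_fixture(rng):
    """Genome with two identical single-exon isoforms at one locus, one
    isoform with a private exon, and a segment duplicated on another
    chromosome."""
    seqs = random_genome(rng, {"chr1": 700, "chr2": 300})
    # duplicate chr1[600:650] onto chr2[100:150]
    c1, c2 = seqs["chr1"], seqs["chr2"]
    seqs["chr2"] = c2[:100] + c1[600:650] + c2[150:]
    shared = (100, 180)
    twins = [
        TranscriptModel("TWIN.1", "TWIN", "chr1", "+", (shared,)),
        TranscriptModel("TWIN.2", "TWIN", "chr1", "+", (shared,)),
    ]
    private = TranscriptModel("PRIV.1", "PRIV", "chr1", "+", ((300, 360), (420, 480)))
    partner = TranscriptModel("PRIV.2", "PRIV", "chr1", "+", ((300, 360),))
    repeat_tx = TranscriptModel("REP.1", "REP", "chr1", "+", ((595, 655),))
    return seqs, twins + [private, partner, repeat_tx]


class TestTranscriptMUL:
    KMIN, KMAX = 10, 40

    @pytest.fixture
    def built(self, rng):
        seqs, transcripts = _tx_fixture(rng)
        index, models = build_combined_index(seqs, transcripts)
        return seqs, transcripts, index, models

    def _mul(self, built, tid, level, rule="coordinate"):
        _, transcripts, index, models = built
        t = models[tid]
        return compute_transcript_mul(
            index, t, models, level=level, kmin=self.KMIN, kmax=self.KMAX,
            transcript_rule=rule,
        ).values

    def test_identical_isoforms_gene_finite_transcript_zero(self, built):
        gene = self._mul(built, "TWIN.1", "gene")
        tx_single = self._mul(built, "TWIN.1", "transcript", "single_source")
        assert np.any(gene > 0)
        assert not np.any(tx_single > 0)

    def test_private_exon_has_transcript_level_uniqueness(self, built):
        tx = self._mul(built, "PRIV.1", "transcript", "single_source")
        # private exon occupies spliced coords [60, 120)
        assert np.any(tx[60:] > 0)
        # positions whose longest window cannot reach the private exon
        # cannot identify the isoform
        assert not np.any(tx[: 60 - self.KMAX] > 0)

    def test_duplicated_segment_kills_both_levels(self, built):
        gene = self._mul(built, "REP.1", "gene")
        # REP spans chr1[595,655); the copy covers [600,650): a position
        # whose every window up to KMAX stays inside the repeat maps to
        # chr2 as well at all lengths
        inner = gene[5 : 55 - self.KMAX + 1]
        assert inner.size and not np.any(inner > 0)

    def test_hierarchy_gene_dominates_transcript(self, built):
        for tid in ("TWIN.1", "PRIV.1", "REP.1"):
            for rule in ("coordinate", "single_source"):
                gene = self._mul(built, tid, "gene", rule)
                tx = self._mul(built, tid, "transcript", rule)
                both = (gene > 0) & (tx > 0)
                assert np.all(gene[both] <= tx[both])
                assert not np.any((gene == 0) & (tx > 0))

    def test_junction_spanning_window_can_be_unique(self, rng):
        """A window absent from the genome but present once on a spliced
        transcript is unique — junctions are evaluated on spliced sequence."""
        seqs = random_genome(rng, {"chr1": 500})
        t = TranscriptModel("J.1", "J", "chr1", "+", ((50, 150), (250, 350)))
        index, models = build_combined_index(seqs, [t])
        mul = compute_transcript_mul(index, t, models, level="transcript",
                                     kmin=10, kmax=40)
        junction_window = slice(95, 100)  # starts whose 10-mers straddle 100
        assert np.any(mul.values[junction_window] > 0)
        read = index.sequences["J.1"][95:105]
        assert read not in seqs["chr1"]  # truly genome-absent

    def test_single_exon_no_repeat_matches_genome_mul(self, rng):
        """With one single-exon transcript per locus and no repeats, the
        gene-level transcript MUL equals the genome MUL on the exon."""
        seqs = random_genome(rng, {"chr1": 400})
        t = TranscriptModel("S.1", "S", "chr1", "+", ((100, 200),))
        index, models = build_combined_index(seqs, [t])
        tx_mul = compute_transcript_mul(index, t, models, level="gene",
                                        kmin=10, kmax=40).values
        genome_mul = compute_mul_array(build_index(seqs), "chr1",
                                       kmin=10, kmax=40).values[100:200]
        # positions whose windows stay inside the exon must agree; windows
        # running past the transcript end cannot (the transcript read stops)
        inside = 100 - 40
        assert np.array_equal(tx_mul[:inside], genome_mul[:inside])


class TestOverlaps:
    def test_shared_exon_counts(self):
        a = TranscriptModel("A", "A", "c", "+", ((0, 10),))
        b = TranscriptModel("B", "B", "c", "+", ((5, 15),))
        assert count_overlaps([a, b]) == {"A": 1, "B": 1}

    def test_disjoint(self):
        a = TranscriptModel("A", "A", "c", "+", ((0, 10),))
        b = TranscriptModel("B", "B", "c", "+", ((20, 30),))
        c = TranscriptModel("C", "C", "c2", "+", ((0, 10),))
        assert count_overlaps([a, b, c]) == {"A": 0, "B": 0, "C": 0}

    def test_nested_isoforms(self):
        a = TranscriptModel("A", "G", "c", "+", ((0, 100),))
        b = TranscriptModel("B", "G", "c", "+", ((10, 90),))
        c = TranscriptModel("C", "G", "c", "+", ((20, 80),))
        assert count_overlaps([a, b, c]) == {"A": 2, "B": 2, "C": 2}

    def test_intron_only_overlap_not_counted(self):
        a = TranscriptModel("A", "A", "c", "+", ((0, 10), (90, 100)))
        b = TranscriptModel("B", "B", "c", "+", ((40, 50),))  # inside A's intron
        assert count_overlaps([a, b]) == {"A": 0, "B": 0}
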