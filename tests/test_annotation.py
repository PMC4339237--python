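import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annoquant.annotation import (
    Gene,
    GeneModel,
    Genome,
    GenomicInterval,
    GTFParseError,
    MissingChromosomeError,
    Transcript,
    genome_to_transcript,
    parse_gtf,
    project_to_genome,
    reverse_complement,
    span_length,
    spliced_sequence,
    write_gtf,
)

from .conftest import make_model, make_transcript, random_sequence
from .oracles import project_oracle


class TestGenomicInterval:
    def test_length_single_base(self):
        assert GenomicInterval("chr1", 5, 5).length == 1

    def test_invalid_intervals(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 9)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 1, 5, strand="*")

    def test_span_length_printed_coordinates(self):
        # short nested gene, single exon
        assert span_length(GenomicInterval("chr7", 135_612_022, 135_612_198, "+")) == 177
        assert span_length(GenomicInterval("chr4", 89_442_724, 89_442_940, "-")) == 217

    def test_span_length_additive_over_partition(self):
        whole = GenomicInterval("chr1", 100, 399)
        left = GenomicInterval("chr1", 100, 249)
        right = GenomicInterval("chr1", 250, 399)
        assert span_length(whole) == span_length(left) + span_length(right)


class TestTranscript:
    def test_exons_normalized_ascending(self):
        tx = Transcript(
            "t",
            "G",
            "+",
            (
                GenomicInterval("c", 300, 400, "+"),
                GenomicInterval("c", 100, 200, "+"),
            ),
        )
        assert [e.start for e in tx.exons] == [100, 300]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            Transcript(
                "t",
                "G",
                "+",
                (
                    GenomicInterval("c", 100, 200, "+"),
                    GenomicInterval("c", 150, 300, "+"),
                ),
            )

    def test_spliced_length(self, three_exon_tx):
        assert three_exon_tx.spliced_length == 100 + 120 + 100

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="chromosomes"):
            Transcript(
                "t",
                "G",
                "+",
                (
                    GenomicInterval("c1", 100, 200, "+"),
                    GenomicInterval("c2", 300, 400, "+"),
                ),
            )


class TestGenome:
    def test_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError, match="ACGT"):
            Genome({"c": "ACGTN"})

    def test_case_normalized(self):
        assert Genome({"c": "acgt"})["c"] == "ACGT"

    def test_missing_chromosome_error(self):
        genome = Genome({"c": "ACGT"})
        with pytest.raises(MissingChromosomeError):
            genome["PATCH"]

    def test_fetch_one_based_inclusive(self):
        genome = Genome({"c": "ACGTACGT"})
        assert genome.fetch("c", 2, 4) == "CGT"


class TestParseGtf:
    def test_single_exon_line(self):
        gtf = (
            "chr7\tsrc\texon\t135612022\t135612198\t.\t+\t.\t"
            'gene_id "LUZP6"; transcript_id "ENS-T1";\n'
        )
        model = parse_gtf(io.StringIO(gtf))
        assert set(model.genes) == {"LUZP6"}
        (tx,) = model.genes["LUZP6"].transcripts
        assert tx.spliced_length == 177

    def test_empty_stream(self):
        model = parse_gtf(io.StringIO(""))
        assert len(model.genes) == 0

    def test_non_exon_features_ignored(self):
        gtf = (
            "c\ts\tCDS\t10\t50\t.\t+\t.\tgene_id \"G\"; transcript_id \"t\";\n"
            "c\ts\texon\t10\t60\t.\t+\t.\tgene_id \"G\"; transcript_id \"t\";\n"
        )
        model = parse_gtf(io.StringIO(gtf))
        assert model.genes["G"].transcripts[0].spliced_length == 51

    @pytest.mark.parametrize(
        "line,match",
        [
            ("c\ts\texon\t10\t60\t.\t+\t.\n", "columns"),
            ("c\ts\texon\t60\t10\t.\t+\t.\tgene_id \"G\"; transcript_id \"t\";\n", "end"),
            ("c\ts\texon\t10\t60\t.\t?\t.\tgene_id \"G\"; transcript_id \"t\";\n", "strand"),
        ],
    )
    def test_malformed_lines_name_line_number(self, line, match):
        with pytest.raises(GTFParseError, match="line 1"):
            parse_gtf(io.StringIO(line))


@st.composite
def gene_models(draw):
    n_genes = draw(st.integers(1, 4))
    model = GeneModel("rand")
    cursor = 1
    for gi in range(n_genes):
        symbol = f"G{gi}"
        strand = draw(st.sampled_from("+-"))
        n_tx = draw(st.integers(1, 2))
        txs = []
        start_of_gene = cursor
        for ti in range(n_tx):
            cursor = start_of_gene
            exons = []
            for _ in range(draw(st.integers(1, 4))):
                length = draw(st.integers(1, 50))
                exons.append(GenomicInterval("chrR", cursor, cursor + length - 1, strand))
                cursor += length + draw(st.integers(2, 30))
            txs.append(Transcript(f"G{gi}.t{ti}", symbol, strand, tuple(exons)))
        cursor += 100
        model.add_gene(Gene(symbol, tuple(txs)))
    return model


class TestGtfRoundTrip:
    @given(gene_models())
    @settings(max_examples=40, deadline=None)
    def test_write_parse_round_trip(self, model):
        buf = io.StringIO()
        write_gtf(model, buf)
        reparsed = parse_gtf(io.StringIO(buf.getvalue()))
        assert reparsed == model
        # counts preserved
        assert len(reparsed.genes) == len(model.genes)
        assert sum(1 for _ in reparsed.transcripts()) == sum(
            1 for _ in model.transcripts()
        )


class TestSplicedSequence:
    def test_single_exon_plus(self, toy_genome):
        tx = make_transcript("t", "G", "+", [(11, 40)])
        assert spliced_sequence(toy_genome, tx) == toy_genome.fetch("chrT", 11, 40)

    def test_single_exon_minus(self, toy_genome):
        tx = make_transcript("t", "G", "-", [(11, 40)])
        assert spliced_sequence(toy_genome, tx) == reverse_complement(
            toy_genome.fetch("chrT", 11, 40)
        )

    def test_three_exon_manual_slicing(self, toy_genome, three_exon_tx):
        manual = (
            toy_genome.fetch("chrT", 101, 200)
            + toy_genome.fetch("chrT", 301, 420)
            + toy_genome.fetch("chrT", 601, 700)
        )
        assert spliced_sequence(toy_genome, three_exon_tx) == manual
        assert len(manual) == three_exon_tx.spliced_length

    def test_minus_strand_is_revcomp_of_concatenation(self, toy_genome, minus_tx):
        manual = toy_genome.fetch("chrT", 1001, 1100) + toy_genome.fetch(
            "chrT", 1301, 1400
        )
        assert spliced_sequence(toy_genome, minus_tx) == reverse_complement(manual)

    def test_absent_chromosome_raises(self, three_exon_tx):
        with pytest.raises(MissingChromosomeError):
            spliced_sequence(Genome({"other": "ACGT"}), three_exon_tx)


class TestProjectToGenome:
    def test_window_inside_one_exon(self, three_exon_tx):
        blocks = project_to_genome(three_exon_tx, 10, 20)
        assert blocks == (GenomicInterval("chrT", 111, 130, "+"),)

    def test_window_straddles_first_junction(self, three_exon_tx):
        # exon 1 is 100 bp; a window covering transcript bases 90..109
        blocks = project_to_genome(three_exon_tx, 90, 20)
        assert blocks == project_oracle(three_exon_tx, 90, 20)
        assert blocks[0].end == 200 and blocks[1].start == 301

    def test_minus_strand_offset_zero_in_highest_exon(self, minus_tx):
        blocks = project_to_genome(minus_tx, 0, 10)
        assert blocks == (GenomicInterval("chrT", 1391, 1400, "-"),)

    def test_out_of_range(self, three_exon_tx):
        with pytest.raises(ValueError):
            project_to_genome(three_exon_tx, 310, 20)
        with pytest.raises(ValueError):
            project_to_genome(three_exon_tx, -1, 20)

    @given(st.integers(0, 319), st.integers(1, 320))
    @settings(max_examples=200, deadline=None)
    def test_matches_per_base_oracle_plus(self, offset, length):
        tx = make_transcript("TX1", "GA", "+", [(101, 200), (301, 420), (601, 700)])
        if offset + length > tx.spliced_length:
            return
        assert project_to_genome(tx, offset, length) == project_oracle(
            tx, offset, length
        )

    @given(st.integers(0, 199), st.integers(1, 200))
    @settings(max_examples=200, deadline=None)
    def test_matches_per_base_oracle_minus(self, offset, length):
        tx = make_transcript("TX2", "GB", "-", [(1001, 1100), (1301, 1400)])
        if offset + length > tx.spliced_length:
            return
        assert project_to_genome(tx, offset, length) == project_oracle(
            tx, offset, length
        )

    def test_sequence_round_trip(self, toy_genome, three_exon_tx, minus_tx):
        # genome sequence over the projected blocks equals the mRNA substring
        for tx in (three_exon_tx, minus_tx):
            mrna = spliced_sequence(toy_genome, tx)
            for offset, length in [(0, 30), (85, 40), (tx.spliced_length - 25, 25)]:
                blocks = project_to_genome(tx, offset, length)
                seq = "".join(toy_genome.fetch(b.chrom, b.start, b.end) for b in blocks)
                if tx.strand == "-":
                    seq = reverse_complement(seq)
                assert seq == mrna[offset : offset + length]

    def test_genome_to_transcript_inverse(self, three_exon_tx, minus_tx):
        from .oracles import transcript_base_coords

        for tx in (three_exon_tx, minus_tx):
            coords = transcript_base_coords(tx)
            for t_pos, g_pos in enumerate(coords):
                assert genome_to_transcript(tx, g_pos) == t_pos
            assert genome_to_transcript(tx, 999_999) is None
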