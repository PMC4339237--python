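import io

import numpy as np
import pytest

from annoquant.annotation import Genome, GenomicInterval, spliced_sequence
from annoquant.mapper import (
    Alignment,
    MappingResult,
    SpliceParams,
    GenomeMapper,
    TranscriptomeMapper,
    default_max_mismatch,
    map_sequential,
    map_to_genome,
    map_to_transcriptome,
    ml_status,
    read_sam,
    write_sam,
)

from .conftest import make_model, make_transcript, random_sequence
from .oracles import genome_map_oracle, transcriptome_map_oracle

SPLICE = SpliceParams(min_anchor=10, min_intron=20, max_intron=10_000)


def placement_keys(result: MappingResult) -> frozenset:
    return frozenset(a.placement_key() for a in result.alignments)


@pytest.fixture
def world(rng):
    genome = Genome({"chrT": random_sequence(rng, 8000)})
    tx = make_transcript("TX1", "GA", "+", [(1001, 1100), (1601, 1700), (2201, 2300)])
    model = make_model("toy", tx)
    return genome, model, tx


class TestMlStatus:
    @pytest.mark.parametrize("ml,expected", [(0, "unmapped"), (1, "unique"), (7, "multiple")])
    def test_thresholds(self, ml, expected):
        blocks = (GenomicInterval("c", 1, 50),)
        alns = tuple(
            Alignment("r", "c", "+", (GenomicInterval("c", 1 + 100 * i, 50 + 100 * i),), 0)
            for i in range(ml)
        )
        assert ml_status(MappingResult("r", "none", alns)) == expected


class TestDefaults:
    def test_max_mismatch_by_read_length(self):
        assert default_max_mismatch(50) == 1
        assert default_max_mismatch(75) == 2


class TestTranscriptomeMapping:
    def test_exonic_read_unique_one_block(self, world):
        genome, model, tx = world
        read = genome.fetch("chrT", 1020, 1069)
        res = map_to_transcriptome(("r1", read), model, genome, 1)
        assert res.ml == 1
        assert res.best.blocks == (GenomicInterval("chrT", 1020, 1069, "+"),)
        assert not res.best.is_junction

    def test_junction_read_blocks_abut_exon_boundary(self, world):
        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        read = mrna[80:130]  # crosses the exon1/exon2 boundary at offset 100
        res = map_to_transcriptome(("r1", read), model, genome, 1)
        assert res.ml == 1
        b1, b2 = res.best.blocks
        assert b1 == GenomicInterval("chrT", 1081, 1100, "+")
        assert b2 == GenomicInterval("chrT", 1601, 1630, "+")
        assert res.best.is_junction

    def test_reverse_complement_read_found(self, world):
        genome, model, tx = world
        from annoquant.annotation import reverse_complement

        read = reverse_complement(genome.fetch("chrT", 1020, 1069))
        res = map_to_transcriptome(("r1", read), model, genome, 1)
        assert res.ml == 1
        assert res.best.strand == "-"

    def test_duplicated_locus_in_richer_model(self, rng):
        # one genomic repeat; model A annotates one copy, model B both
        core = random_sequence(rng, 300)
        genome = Genome({"chrT": random_sequence(rng, 500) + core
                         + random_sequence(rng, 700) + core + random_sequence(rng, 500)})
        t1 = make_transcript("ta", "GB1", "+", [(501, 800)])
        t2 = make_transcript("tb", "GB2", "+", [(1501, 1800)])
        model_a = make_model("a", t1)
        model_b = make_model("b", t1, t2)
        read = genome.fetch("chrT", 550, 599)
        assert map_to_transcriptome(("r", read), model_a, genome, 1).ml == 1
        assert map_to_transcriptome(("r", read), model_b, genome, 1).ml == 2

    def test_isoform_collapse_does_not_inflate_ml(self, world):
        genome, model, tx = world
        iso = make_transcript(
            "TX1b", "GA", "+", [(1001, 1100), (1601, 1700), (2201, 2300), (2601, 2650)]
        )
        richer = make_model("iso", tx, iso)
        read = genome.fetch("chrT", 1020, 1069)  # shared exon 1 region
        res = map_to_transcriptome(("r", read), richer, genome, 1)
        assert res.ml == 1

    def test_empty_model_everything_unmapped(self, world):
        genome, _, _ = world
        from annoquant.annotation import GeneModel

        res = map_to_transcriptome(("r", "ACGT" * 12), GeneModel("empty"), genome, 1)
        assert res.ml == 0

    def test_mismatch_stratum(self, world):
        genome, model, tx = world
        read = list(genome.fetch("chrT", 1020, 1069))
        read[25] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[25]]
        res = map_to_transcriptome(("r", "".join(read)), model, genome, 2)
        assert res.ml == 1
        assert res.best.mismatches == 1


class TestGenomeMapping:
    def test_non_junction_read_same_as_transcriptome(self, world):
        genome, model, _ = world
        read = genome.fetch("chrT", 1020, 1069)
        via_tx = map_to_transcriptome(("r", read), model, genome, 1)
        via_ge = map_to_genome(("r", read), genome, 1, SPLICE)
        assert placement_keys(via_tx) == placement_keys(via_ge)

    def test_short_overhang_junction_read_unmapped(self, world):
        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        # 4 bases beyond the first junction: overhang < min_anchor on one side
        read = mrna[54:104]
        res = map_to_genome(("r", read), genome, 1, SPLICE)
        assert res.ml == 0
        assert ml_status(res) == "unmapped"

    def test_junction_read_with_good_anchors_recovers_blocks(self, world):
        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        read = mrna[80:130]  # 20 + 30 split around junction
        res = map_to_genome(("r", read), genome, 1, SPLICE)
        assert res.ml == 1
        assert res.best.blocks == (
            GenomicInterval("chrT", 1081, 1100, "+"),
            GenomicInterval("chrT", 1601, 1630, "+"),
        )

    def test_contiguous_preferred_over_spliced_at_equal_mismatches(self, rng):
        # a genome containing both the spliced mRNA copy and the exonic locus:
        # junction reads place contiguously on the mRNA copy and the spliced
        # candidate at the source locus is discarded
        genome = Genome({"chrT": random_sequence(rng, 4000)})
        tx = make_transcript("t", "G", "+", [(501, 700), (1201, 1400)])
        mrna = spliced_sequence(genome, tx)
        insert_at = genome.length_of("chrT") + 201
        genome.append("chrT", random_sequence(rng, 200) + mrna)
        read = mrna[180:230]  # junction read
        res = map_to_genome(("r", read), genome, 1, SPLICE)
        assert res.ml == 1
        assert len(res.best.blocks) == 1
        assert res.best.start == insert_at + 180

    def test_retrocopy_makes_nonjunction_reads_multiple(self, rng):
        genome = Genome({"chrT": random_sequence(rng, 4000)})
        tx = make_transcript("t", "G", "+", [(501, 700), (1201, 1400)])
        mrna = spliced_sequence(genome, tx)
        genome.append("chrT", random_sequence(rng, 200) + mrna)
        read = mrna[50:100]  # fully inside exon 1
        res = map_to_genome(("r", read), genome, 1, SPLICE)
        assert res.ml >= 2

    def test_determinism_and_canonical_order(self, world):
        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        for read in (mrna[80:130], mrna[10:60]):
            r1 = map_to_genome(("r", read), genome, 2, SPLICE)
            r2 = map_to_genome(("r", read), genome, 2, SPLICE)
            assert r1 == r2
            order = [(a.chrom, a.start, a.strand) for a in r1.alignments]
            assert order == sorted(order)


class TestSequentialMode:
    def test_transcriptome_hit_passes_through(self, world):
        genome, model, _ = world
        read = genome.fetch("chrT", 1020, 1069)
        seq = map_sequential(("r", read), model, genome, 1, SPLICE)
        tx_only = map_to_transcriptome(("r", read), model, genome, 1)
        assert seq.mode == "transcriptome_plus_genome"
        assert placement_keys(seq) == placement_keys(tx_only)

    def test_unannotated_read_falls_through_to_genome(self, world):
        genome, model, _ = world
        read = genome.fetch("chrT", 4001, 4050)  # intergenic
        assert map_to_transcriptome(("r", read), model, genome, 1).ml == 0
        seq = map_sequential(("r", read), model, genome, 1, SPLICE)
        assert seq.ml == 1
        assert seq.best.start == 4001

    def test_mapped_fraction_dominates_transcriptome_only(self, world, rng):
        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        reads = [("t%d" % i, mrna[i * 7 : i * 7 + 50]) for i in range(20)]
        reads += [("g%d" % i, genome.fetch("chrT", 3001 + i * 60, 3050 + i * 60)) for i in range(10)]
        reads += [("n%d" % i, random_sequence(rng, 50)) for i in range(5)]
        tx_mapped = sum(
            map_to_transcriptome(r, model, genome, 1).ml >= 1 for r in reads
        )
        seq_mapped = sum(
            map_sequential(r, model, genome, 1, SPLICE).ml >= 1 for r in reads
        )
        assert seq_mapped >= tx_mapped


class TestOracleEquivalence:
    """Small-scale oracle agreement; the full 20-genome sweep lives in
    test_acceptance.py."""

    def test_genome_mode_matches_brute_force(self, rng):
        genome = Genome({"chrT": random_sequence(rng, 6000)})
        tx = make_transcript("t", "G", "+", [(501, 650), (901, 1050), (1301, 1450)])
        mrna = spliced_sequence(genome, tx)
        reads = []
        for i in range(0, len(mrna) - 50, 13):
            reads.append(mrna[i : i + 50])
        for i in range(25):
            reads.append(random_sequence(rng, 50))
        # reads with injected errors
        for i in range(0, len(mrna) - 50, 37):
            arr = list(mrna[i : i + 50])
            arr[17] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[17]]
            reads.append("".join(arr))
        for j, read in enumerate(reads):
            got = placement_keys(map_to_genome((f"r{j}", read), genome, 1, SPLICE))
            expected = genome_map_oracle(genome, read, 1, 10, 20, 10_000)
            assert got == expected, f"read {j}"

    def test_transcriptome_mode_matches_brute_force(self, rng):
        genome = Genome({"chrT": random_sequence(rng, 6000)})
        t1 = make_transcript("t1", "G1", "+", [(501, 650), (901, 1050)])
        t2 = make_transcript("t2", "G2", "-", [(2001, 2200), (2501, 2700)])
        model = make_model("m", t1, t2)
        seqs = [spliced_sequence(genome, t) for t in (t1, t2)]
        reads = []
        for s in seqs:
            for i in range(0, len(s) - 50, 11):
                reads.append(s[i : i + 50])
        for i in range(20):
            reads.append(random_sequence(rng, 50))
        for j, read in enumerate(reads):
            got = placement_keys(map_to_transcriptome((f"r{j}", read), model, genome, 1))
            expected = transcriptome_map_oracle(genome, model, read, 1)
            assert got == expected, f"read {j}"


class TestSamIO:
    def test_round_trip(self, world):
        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        reads = [("r1", mrna[80:130]), ("r2", genome.fetch("chrT", 1020, 1069)),
                 ("r3", "A" * 50)]
        results = [map_to_transcriptome(r, model, genome, 1) for r in reads]
        buf = io.StringIO()
        write_sam(results, {"chrT": genome.length_of("chrT")}, buf, dict(reads))
        back = read_sam(io.StringIO(buf.getvalue()))
        assert len(back) == len(results)
        for orig, rt in zip(results, back):
            assert rt.read_id == orig.read_id
            assert rt.ml == orig.ml
            assert frozenset(a.placement_key() for a in rt.alignments) == frozenset(
                a.placement_key() for a in orig.alignments
            )

    def test_junction_cigar_has_n_run(self, world):
        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        res = map_to_transcriptome(("r1", mrna[80:130]), model, genome, 1)
        buf = io.StringIO()
        write_sam([res], {"chrT": genome.length_of("chrT")}, buf)
        body = [l for l in buf.getvalue().splitlines() if not l.startswith("@")]
        assert "20M500N30M" in body[0]

    def test_sam_parses_with_pysam(self, world, tmp_path):
        import pysam

        genome, model, tx = world
        mrna = spliced_sequence(genome, tx)
        reads = [("r1", mrna[80:130])]
        results = [map_to_transcriptome(r, model, genome, 1) for r in reads]
        path = str(tmp_path / "out.sam")
        write_sam(results, {"chrT": genome.length_of("chrT")}, path, dict(reads))
        with pysam.AlignmentFile(path, "r") as sam:
            records = list(sam)
        assert records[0].cigarstring == "20M500N30M"
        assert records[0].get_tag("XO") == "transcriptome_only"
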