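"""Synthetic genomes, paired annotations and reads with ground truth.

The annotation pair embeds the structural-difference archetypes that drive
annotation-dependent mapping and counting:

* ``identical`` — same gene definition in both models;
* ``three_prime_extension`` — model A's final exon extends past model B's;
* ``nested_gene_vs_shared_transcript`` — model A nests a short gene inside a
  host gene's exon; model B gives both symbols one identical transcript;
* ``absent_chromosome`` — model B places the gene on a patch scaffold the
  genome does not contain;
* ``model_unique_gene`` — the gene exists in only one model;
* ``processed_retrocopy`` — the gene's spliced mRNA is reinserted into the
  genome as an intronless copy; the richer model B annotates the copy too.

Reads are sampled uniformly along transcripts (transcript choice is
proportional to expression weight x spliced length, emulating shotgun
coverage), with independent per-base substitution errors.  Every read
carries a ground-truth record with its origin blocks and junction flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .annotation import (
    Gene,
    GeneModel,
    Genome,
    GenomicInterval,
    Transcript,
    project_to_genome,
    spliced_sequence,
)

__all__ = [
    "ArchetypeSpec",
    "ReadTruth",
    "GenerationError",
    "ARCHETYPES",
    "generate_genome",
    "generate_annotation_pair",
    "simulate_reads",
    "write_fastq",
    "read_fastq",
    "write_truth_tsv",
    "read_truth_tsv",
]

ARCHETYPES = (
    "identical",
    "three_prime_extension",
    "nested_gene_vs_shared_transcript",
    "absent_chromosome",
    "model_unique_gene",
    "processed_retrocopy",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(ValueError):
    """Raised when the requested structures do not fit the genome."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """Size parameters for one generated gene (or gene pair)."""

    archetype: str
    n_exons: int = 4
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (200, 800)
    extension_length: int = 400
    nested_length: int = 180
    present_in: str = "a"  # for model_unique_gene

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        for lo, hi in (self.exon_length, self.intron_length):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.extension_length < 1 or self.nested_length < 1:
            raise ValueError("all lengths must be positive")
        if self.present_in not in ("a", "b"):
            raise ValueError("present_in must be 'a' or 'b'")


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    transcript_id: str
    gene_symbol: str
    offset: int  # 0-based along the mature transcript
    blocks: tuple[GenomicInterval, ...]
    is_junction: bool
    error_positions: tuple[int, ...]

    def placement_key(self) -> tuple:
        return (
            self.blocks[0].chrom,
            self.blocks[0].strand,
            tuple((b.start, b.end) for b in self.blocks),
        )


def generate_genome(chrom_lengths: Sequence[int], seed: int) -> Genome:
    """Uniform random A/C/G/T chromosomes named chr1, chr2, ..."""
    if any(n < 1 for n in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    genome = Genome()
    for i, n in enumerate(chrom_lengths, start=1):
        codes = rng.integers(0, 4, size=n)
        genome[f"chr{i}"] = _BASES[codes].tobytes().decode("ascii")
    return genome


class _Layout:
    """Allocates non-overlapping slots along chromosomes, round-robin."""

    def __init__(self, genome: Genome, margin: int = 600):
        self.genome = genome
        self.margin = margin
        self.chroms = sorted(genome.keys())
        self.lengths = {c: len(genome[c]) for c in self.chroms}
        self.cursor = {c: margin + 1 for c in self.chroms}
        self._cycle = itertools.cycle(self.chroms)

    def reserve(self, span: int) -> tuple[str, int]:
        """Returns (chrom, 1-based start) of a free region of `span` bp."""
        for _ in range(len(self.chroms)):
            chrom = next(self._cycle)
            start = self.cursor[chrom]
            if start + span + self.margin <= self.lengths[chrom]:
                self.cursor[chrom] = start + span + self.margin
                return chrom, start
        raise GenerationError(
            f"insufficient genome space for a {span} bp feature"
        )


def _draw_exons(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    strand: str,
    n_exons: int,
    exon_rng: tuple[int, int],
    intron_rng: tuple[int, int],
) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i in range(n_exons):
        elen = int(rng.integers(exon_rng[0], exon_rng[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + elen - 1, strand))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(intron_rng[0], intron_rng[1] + 1))
    return tuple(exons)


def _gene_footprint(spec: ArchetypeSpec) -> int:
    """Upper bound on the genomic span one generated gene can occupy."""
    return (
        spec.n_exons * spec.exon_length[1]
        + max(0, spec.n_exons - 1) * spec.intron_length[1]
        + spec.extension_length
    )


def generate_annotation_pair(
    genome: Genome, specs: Sequence[ArchetypeSpec], seed: int
) -> tuple[GeneModel, GeneModel, list[dict]]:
    """Build two gene models over `genome` differing exactly per `specs`.

    The genome is modified in place for ``processed_retrocopy`` (the spliced
    mRNA is appended, with a random spacer, to the source chromosome).
    Returns (model_a, model_b, truth table); each truth row records the
    symbol(s) and archetype of one generated locus.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    layout = _Layout(genome)
    model_a = GeneModel("model_a")
    model_b = GeneModel("model_b")
    truth: list[dict] = []

    for idx, spec in enumerate(specs, start=1):
        tag = spec.archetype.split("_")[0].upper()[:6]
        symbol = f"G{idx:03d}{tag}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        chrom, start = layout.reserve(_gene_footprint(spec))
        draw_start = start
        if spec.archetype == "three_prime_extension" and strand == "-":
            # keep room inside the reserved slot for the leftward 3' extension
            draw_start = start + spec.extension_length
        exons = _draw_exons(
            rng, chrom, draw_start, strand, spec.n_exons, spec.exon_length, spec.intron_length
        )
        row: dict = {"symbol": symbol, "archetype": spec.archetype, "chrom": chrom}

        if spec.archetype == "identical":
            for model, suffix in ((model_a, "a"), (model_b, "b")):
                tx = Transcript(f"{symbol}.t{suffix}", symbol, strand, exons)
                model.add_gene(Gene(symbol, (tx,)))

        elif spec.archetype == "three_prime_extension":
            # model A carries the 3'-extended final exon
            ext = spec.extension_length
            exts = list(exons)
            if strand == "+":
                last = exts[-1]
                exts[-1] = GenomicInterval(chrom, last.start, last.end + ext, strand)
            else:
                first = exts[0]
                new_start = first.start - ext
                if new_start < 1:
                    raise GenerationError("extension would run off the chromosome")
                exts[0] = GenomicInterval(chrom, new_start, first.end, strand)
            model_a.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.ta", symbol, strand, tuple(exts)),))
            )
            model_b.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.tb", symbol, strand, exons),))
            )
            row["extension_length"] = ext

        elif spec.archetype == "nested_gene_vs_shared_transcript":
            nested_symbol = f"{symbol}N"
            host_exon = max(exons, key=lambda e: e.length)
            if host_exon.length < spec.nested_length + 2:
                raise GenerationError(
                    "host exon too short to nest a "
                    f"{spec.nested_length} bp gene; widen exon_length"
                )
            pad = (host_exon.length - spec.nested_length) // 2
            nested_exon = GenomicInterval(
                chrom,
                host_exon.start + pad,
                host_exon.start + pad + spec.nested_length - 1,
                strand,
            )
            # model A: host gene + short nested gene inside one exon
            model_a.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.ta", symbol, strand, exons),))
            )
            model_a.add_gene(
                Gene(
                    nested_symbol,
                    (Transcript(f"{nested_symbol}.ta", nested_symbol, strand, (nested_exon,)),),
                )
            )
            # model B: both symbols share one identical (bicistronic) transcript
            model_b.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.tb", symbol, strand, exons),))
            )
            model_b.add_gene(
                Gene(
                    nested_symbol,
                    (Transcript(f"{nested_symbol}.tb", nested_symbol, strand, exons),),
                )
            )
            row["nested_symbol"] = nested_symbol

        elif spec.archetype == "absent_chromosome":
            patch = f"{symbol}_PATCH"
            shifted = tuple(
                GenomicInterval(patch, e.start - start + 1001, e.end - start + 1001, strand)
                for e in exons
            )
            model_a.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.ta", symbol, strand, exons),))
            )
            model_b.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.tb", symbol, strand, shifted),))
            )
            row["patch_chrom"] = patch

        elif spec.archetype == "model_unique_gene":
            target = model_a if spec.present_in == "a" else model_b
            suffix = spec.present_in
            target.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.t{suffix}", symbol, strand, exons),))
            )
            row["present_in"] = spec.present_in

        elif spec.archetype == "processed_retrocopy":
            source_tx_a = Transcript(f"{symbol}.ta", symbol, strand, exons)
            model_a.add_gene(Gene(symbol, (source_tx_a,)))
            model_b.add_gene(
                Gene(symbol, (Transcript(f"{symbol}.tb", symbol, strand, exons),))
            )
            mrna = spliced_sequence(genome, source_tx_a)
            spacer = _BASES[rng.integers(0, 4, size=500)].tobytes().decode("ascii")
            insert_at = genome.length_of(chrom) + len(spacer) + 1
            genome.append(chrom, spacer + mrna)
            retro_symbol = f"{symbol}RC"
            retro_exon = GenomicInterval(
                chrom, insert_at, insert_at + len(mrna) - 1, "+"
            )
            model_b.add_gene(
                Gene(
                    retro_symbol,
                    (Transcript(f"{retro_symbol}.tb", retro_symbol, "+", (retro_exon,)),),
                )
            )
            row["retro_symbol"] = retro_symbol
            row["retro_start"] = insert_at

        truth.append(row)

    return model_a, model_b, truth


def simulate_reads(
    genome: Genome,
    model: GeneModel,
    expression_weights: Mapping[str, float] | None,
    n_reads: int,
    read_length: int,
    error_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Simulate single-end reads with uniform fragment sampling.

    Weights may be keyed by transcript id or gene symbol (transcript wins);
    missing keys default to 1.  Sampling probability is weight x spliced
    length; the start offset is uniform over the valid range.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    weights = expression_weights or {}
    candidates: list[Transcript] = []
    probs: list[float] = []
    for tx in model.transcripts():
        if tx.chrom not in genome or tx.spliced_length < read_length:
            continue
        w = float(weights.get(tx.id, weights.get(tx.gene_symbol, 1.0)))
        if w < 0:
            raise ValueError(f"negative weight for {tx.id}")
        if w > 0:
            candidates.append(tx)
            probs.append(w * tx.spliced_length)
    if not candidates:
        raise GenerationError(
            f"no transcript of spliced length >= {read_length} with positive weight"
        )
    p = np.asarray(probs, dtype=float)
    p /= p.sum()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    tx_idx = rng.choice(len(candidates), size=n_reads, p=p)
    seq_cache = {tx.id: spliced_sequence(genome, tx) for tx in candidates}

    reads: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    for i in range(n_reads):
        tx = candidates[tx_idx[i]]
        mrna = seq_cache[tx.id]
        offset = int(rng.integers(0, tx.spliced_length - read_length + 1))
        raw = mrna[offset : offset + read_length]
        errors: tuple[int, ...] = ()
        if error_rate > 0:
            mask = rng.random(read_length) < error_rate
            if mask.any():
                arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8).copy()
                positions = np.flatnonzero(mask)
                for pos in positions:
                    choices = _BASES[_BASES != arr[pos]]
                    arr[pos] = choices[int(rng.integers(0, len(choices)))]
                raw = arr.tobytes().decode("ascii")
                errors = tuple(int(x) for x in positions)
        read_id = f"r{i:06d}"
        blocks = project_to_genome(tx, offset, read_length)
        reads.append((read_id, raw))
        truths.append(
            ReadTruth(
                read_id=read_id,
                transcript_id=tx.id,
                gene_symbol=tx.gene_symbol,
                offset=offset,
                blocks=blocks,
                is_junction=len(blocks) >= 2,
                error_positions=errors,
            )
        )
    return reads, truths


# ---------------------------------------------------------------------------
# FASTQ / truth-table I/O


def write_fastq(reads: Sequence[tuple[str, str]], dest: IO[str] | str) -> None:
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_fastq(reads, fh)
        return
    for read_id, seq in reads:
        dest.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]


def write_truth_tsv(truths: Sequence[ReadTruth], dest: IO[str] | str) -> None:
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_truth_tsv(truths, fh)
        return
    dest.write(
        "read_id\ttranscript_id\tgene_symbol\toffset\tchrom\tstrand\t"
        "blocks\tis_junction\terror_positions\n"
    )
    for t in truths:
        blocks = ",".join(f"{b.start}-{b.end}" for b in t.blocks)
        errs = ",".join(str(e) for e in t.error_positions)
        dest.write(
            f"{t.read_id}\t{t.transcript_id}\t{t.gene_symbol}\t{t.offset}\t"
            f"{t.blocks[0].chrom}\t{t.blocks[0].strand}\t{blocks}\t"
            f"{int(t.is_junction)}\t{errs}\n"
        )


def read_truth_tsv(path: str) -> list[ReadTruth]:
    out: list[ReadTruth] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            (
                read_id,
                tx_id,
                symbol,
                offset,
                chrom,
                strand,
                blocks_s,
                is_junction,
                errs,
            ) = line.rstrip("\n").split("\t")
            blocks = tuple(
                GenomicInterval(chrom, int(b.split("-")[0]), int(b.split("-")[1]), strand)
                for b in blocks_s.split(",")
            )
            out.append(
                ReadTruth(
                    read_id=read_id,
                    transcript_id=tx_id,
                    gene_symbol=symbol,
                    offset=int(offset),
                    blocks=blocks,
                    is_junction=bool(int(is_junction)),
                    error_positions=tuple(int(e) for e in errs.split(",") if e),
                )
            )
    return out
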