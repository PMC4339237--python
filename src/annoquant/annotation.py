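"""Genomes, gene models, GTF/FASTA I/O and transcript<->genome coordinate maps.

Coordinate convention: all externally visible coordinates are GTF-style,
1-based and inclusive on both ends.  Transcript ("spliced") coordinates are
0-based offsets along the mature mRNA in transcription order (position 0 is
the transcript 5' end, which on the '-' strand lies in the
highest-genomic-coordinate exon).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "Transcript",
    "Gene",
    "GeneModel",
    "Genome",
    "GTFParseError",
    "MissingChromosomeError",
    "parse_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "span_length",
    "spliced_sequence",
    "project_to_genome",
    "genome_to_transcript",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


class MissingChromosomeError(KeyError):
    """A transcript references a chromosome absent from the genome.

    This situation is meaningful, not merely an error: annotations may place
    genes on patch scaffolds that a given genome build does not contain.
    """


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def span_length(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    return interval.end - interval.start + 1


@dataclass(frozen=True)
class Transcript:
    """A transcript: ordered, non-overlapping exons on one chromosome/strand.

    Exons are stored in ascending genomic order regardless of strand.
    """

    id: str
    gene_symbol: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.id}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.id} spans chromosomes {chroms}")
        for a, b in zip(exons, exons[1:]):
            if a.end >= b.start:
                raise ValueError(f"overlapping exons in transcript {self.id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1

    def structure_key(self) -> tuple:
        """Hashable identity of the exon-level structure (ignores ids)."""
        return (self.chrom, self.strand, tuple((e.start, e.end) for e in self.exons))


@dataclass(frozen=True)
class Gene:
    """A gene: a symbol and a non-empty list of transcripts sharing it."""

    symbol: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.symbol} has no transcripts")
        for t in self.transcripts:
            if t.gene_symbol != self.symbol:
                raise ValueError(
                    f"transcript {t.id} carries symbol {t.gene_symbol}, "
                    f"expected {self.symbol}"
                )

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(t.chrom for t in self.transcripts)

    def span(self, chrom: str | None = None) -> GenomicInterval:
        """Gene span (min start .. max end) on `chrom`, or the sole chromosome."""
        if chrom is None:
            chroms = self.chromosomes
            if len(chroms) != 1:
                raise ValueError(
                    f"gene {self.symbol} spans several chromosomes; pass chrom"
                )
            chrom = next(iter(chroms))
        txs = [t for t in self.transcripts if t.chrom == chrom]
        if not txs:
            raise ValueError(f"gene {self.symbol} has no transcript on {chrom}")
        return GenomicInterval(
            chrom,
            min(t.start for t in txs),
            max(t.end for t in txs),
            txs[0].strand,
        )

    def structure_set(self) -> frozenset[tuple]:
        return frozenset(t.structure_key() for t in self.transcripts)


@dataclass
class GeneModel:
    """A named annotation: genes keyed by symbol."""

    name: str
    genes: dict[str, Gene] = field(default_factory=dict)

    @property
    def chromosomes(self) -> set[str]:
        out: set[str] = set()
        for g in self.genes.values():
            out |= g.chromosomes
        return out

    @property
    def symbols(self) -> set[str]:
        return set(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for symbol in sorted(self.genes):
            yield from self.genes[symbol].transcripts

    def add_gene(self, gene: Gene) -> None:
        if gene.symbol in self.genes:
            raise ValueError(f"duplicate symbol {gene.symbol} in model {self.name}")
        self.genes[gene.symbol] = gene

    def rename_symbols(self, mapping: dict[str, str]) -> "GeneModel":
        """Apply a symbol-harmonization table (identity for absent keys)."""
        out = GeneModel(self.name)
        for symbol in sorted(self.genes):
            new = mapping.get(symbol, symbol)
            gene = self.genes[symbol]
            txs = tuple(
                Transcript(t.id, new, t.strand, t.exons) for t in gene.transcripts
            )
            out.add_gene(Gene(new, txs))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModel):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for sym, gene in self.genes.items():
            a = sorted(t.structure_key() for t in gene.transcripts)
            b = sorted(t.structure_key() for t in other.genes[sym].transcripts)
            if a != b:
                return False
        return True


class Genome:
    """Mutable mapping of chromosome name -> uppercase A/C/G/T sequence.

    A version counter is bumped on every mutation so mapping indexes built
    against a genome can detect staleness.
    """

    def __init__(self, sequences: dict[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        self.version = 0
        if sequences:
            for name, seq in sequences.items():
                self[name] = seq

    @staticmethod
    def _validate(name: str, seq: str) -> str:
        if not seq:
            raise ValueError(f"chromosome {name} has empty sequence")
        seq = seq.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"chromosome {name} contains characters outside ACGT: {sorted(bad)}"
            )
        return seq

    def __setitem__(self, name: str, seq: str) -> None:
        self._seqs[name] = self._validate(name, seq)
        self.version += 1

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise MissingChromosomeError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def keys(self):
        return self._seqs.keys()

    def items(self):
        return self._seqs.items()

    def length_of(self, name: str) -> int:
        return len(self[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        seq = self[chrom]
        if start < 1 or end > len(seq) or end < start:
            raise ValueError(
                f"fetch {chrom}:{start}-{end} out of range (length {len(seq)})"
            )
        return seq[start - 1 : end]

    def append(self, chrom: str, extra: str) -> int:
        """Append sequence to a chromosome; returns the new total length."""
        self._seqs[chrom] = self[chrom] + self._validate(chrom, extra)
        self.version += 1
        return len(self._seqs[chrom])


# ---------------------------------------------------------------------------
# GTF I/O


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GTFParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(source: IO[str] | Iterable[str] | str, name: str = "model") -> GeneModel:
    """Parse exon features from a GTF stream (or path) into a GeneModel.

    Non-exon features (CDS, start/stop codons, ...) are ignored; the gene
    symbol is taken from ``gene_name`` when present, else ``gene_id``.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return parse_gtf(fh, name=name)

    # (symbol, transcript_id) -> [strand, [exons]]
    tx_exons: dict[tuple[str, str], list] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GTFParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        if feature != "exon":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GTFParseError(
                f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from None
        if end < start:
            raise GTFParseError(f"line {lineno}: end {end} < start {start}")
        if strand not in ("+", "-"):
            raise GTFParseError(f"line {lineno}: unknown strand {strand!r}")
        attrs = _parse_attributes(attr_s, lineno)
        symbol = attrs.get("gene_name") or attrs.get("gene_id")
        tx_id = attrs.get("transcript_id")
        if not symbol or not tx_id:
            raise GTFParseError(
                f"line {lineno}: exon lacks gene_id/gene_name or transcript_id"
            )
        entry = tx_exons.setdefault((symbol, tx_id), [strand, []])
        if entry[0] != strand:
            raise GTFParseError(f"line {lineno}: strand conflict in {tx_id}")
        entry[1].append(GenomicInterval(chrom, start, end, strand))

    by_symbol: dict[str, list[Transcript]] = {}
    for (symbol, tx_id), (strand, exons) in tx_exons.items():
        tx = Transcript(tx_id, symbol, strand, tuple(exons))
        by_symbol.setdefault(symbol, []).append(tx)

    model = GeneModel(name)
    for symbol in sorted(by_symbol):
        txs = tuple(sorted(by_symbol[symbol], key=lambda t: (t.start, t.id)))
        model.add_gene(Gene(symbol, txs))
    return model


def write_gtf(model: GeneModel, dest: IO[str] | str) -> None:
    """Write a GeneModel as exon-only GTF lines."""
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_gtf(model, fh)
        return
    for tx in sorted(
        model.transcripts(), key=lambda t: (t.chrom, t.start, t.gene_symbol, t.id)
    ):
        for e in tx.exons:
            attrs = (
                f'gene_id "{tx.gene_symbol}"; transcript_id "{tx.id}"; '
                f'gene_name "{tx.gene_symbol}";'
            )
            dest.write(
                f"{e.chrom}\tannoquant\texon\t{e.start}\t{e.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str) -> Genome:
    genome = Genome()
    for record in SeqIO.parse(path, "fasta"):
        genome[record.id] = str(record.seq)
    if len(genome) == 0:
        raise ValueError(f"no sequences in {path}")
    return genome


def write_fasta(genome: Genome, path: str) -> None:
    records = [
        SeqRecord(Seq(genome[name]), id=name, description="")
        for name in sorted(genome.keys())
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Sequence extraction and coordinate projection


def spliced_sequence(genome: Genome, transcript: Transcript) -> str:
    """Mature mRNA sequence: exon substrings concatenated in genomic order,
    reverse-complemented as a whole for '-' strand transcripts."""
    parts = [genome.fetch(e.chrom, e.start, e.end) for e in transcript.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if transcript.strand == "-" else seq


def project_to_genome(
    transcript: Transcript, offset: int, length: int
) -> tuple[GenomicInterval, ...]:
    """Map a transcript-coordinate window to genomic blocks.

    `offset` is 0-based along the mature transcript (transcription order);
    returns the minimal list of genomic blocks in ascending genomic order.
    Block count >= 2 exactly when the window crosses an exon junction.
    """
    if length < 1:
        raise ValueError(f"window length must be >= 1, got {length}")
    if offset < 0 or offset + length > transcript.spliced_length:
        raise ValueError(
            f"window [{offset}, {offset + length}) outside transcript "
            f"{transcript.id} of spliced length {transcript.spliced_length}"
        )
    exons = (
        transcript.exons
        if transcript.strand == "+"
        else tuple(reversed(transcript.exons))
    )
    blocks: list[GenomicInterval] = []
    pos = offset
    remaining = length
    for exon in exons:
        elen = exon.length
        if pos >= elen:
            pos -= elen
            continue
        take = min(elen - pos, remaining)
        if transcript.strand == "+":
            block = GenomicInterval(
                exon.chrom, exon.start + pos, exon.start + pos + take - 1, "+"
            )
        else:
            block = GenomicInterval(
                exon.chrom, exon.end - pos - take + 1, exon.end - pos, "-"
            )
        blocks.append(block)
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    return tuple(sorted(blocks, key=lambda b: b.start))


def genome_to_transcript(transcript: Transcript, genomic_pos: int) -> int | None:
    """Transcript coordinate (0-based) of a 1-based genomic position, or None
    if the position falls outside every exon."""
    consumed = 0
    exons = (
        transcript.exons
        if transcript.strand == "+"
        else tuple(reversed(transcript.exons))
    )
    for exon in exons:
        if exon.start <= genomic_pos <= exon.end:
            if transcript.strand == "+":
                return consumed + (genomic_pos - exon.start)
            return consumed + (exon.end - genomic_pos)
        consumed += exon.length
    return None


def build_transcriptome(
    genome: Genome, model: GeneModel, warn_stream: IO[str] | None = None
) -> list[tuple[Transcript, str]]:
    """Spliced sequences for every transcript whose chromosome the genome has.

    Transcripts on absent chromosomes (patch scaffolds) are skipped with a
    warning rather than failing the whole build.
    """
    out: list[tuple[Transcript, str]] = []
    for tx in model.transcripts():
        if tx.chrom not in genome:
            stream = warn_stream or sys.stderr
            stream.write(
                f"warning: skipping transcript {tx.id} ({tx.gene_symbol}): "
                f"chromosome {tx.chrom} absent from genome\n"
            )
            continue
        out.append((tx, spliced_sequence(genome, tx)))
    return out
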