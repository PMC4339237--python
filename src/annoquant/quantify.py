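"""Gene-level counting with ambiguity rules, ratio and log-ratio concordance.

Counting rule for a uniquely placed read whose alignment is compatible with
gene set G:

* |G| = 0  — the placement is unannotated; the read is not counted;
* |G| = 1  — one full count to that gene;
* |G| >= 2 — let U be the genes of G that possess at least one
  read-length window of one of their transcripts compatible with them alone
  ("unique region").  If U is non-empty each gene of U receives 1/|U|;
  otherwise every gene of G receives 1/|G|.

So a short gene wholly nested inside another (no unique window) receives
nothing, while two genes sharing an identical transcript split every read
50/50.  Counts are kept as exact fractions; conservation (sum of counts ==
number of annotated unique reads) is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import IO, Iterable, Mapping, Sequence

from .annotation import (
    GeneModel,
    GenomicInterval,
    Transcript,
    genome_to_transcript,
    project_to_genome,
)
from .mapper import Alignment

__all__ = [
    "CountTable",
    "ConcordanceRow",
    "DEConcordance",
    "GeneAssigner",
    "compatible_genes",
    "count_reads",
    "ratio",
    "concordance_table",
    "log2_ratio",
    "de_concordance",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (1.05, 1.10, 1.20, 1.50, 2.0, 5.0, 10.0, 100.0)


def alignment_compatible(transcript: Transcript, blocks: Sequence[GenomicInterval]) -> bool:
    """True if the blocks equal the projection of some window of `transcript`.

    Strand of the alignment is deliberately ignored (unstranded libraries):
    only chromosome and block coordinates must match.
    """
    if blocks[0].chrom != transcript.chrom:
        return False
    length = sum(b.length for b in blocks)
    if length > transcript.spliced_length:
        return False
    # transcript coordinate of the window's 5'-most base (transcription order)
    first_base = blocks[0].start if transcript.strand == "+" else blocks[-1].end
    offset = genome_to_transcript(transcript, first_base)
    if offset is None or offset + length > transcript.spliced_length:
        return False
    expected = project_to_genome(transcript, offset, length)
    return tuple((b.start, b.end) for b in expected) == tuple(
        (b.start, b.end) for b in blocks
    )


class GeneAssigner:
    """Read-to-gene assignment machinery for one model at one read length.

    Caches per-chromosome transcript lists and per-gene "has a unique
    read-length window" flags.
    """

    def __init__(self, model: GeneModel, read_length: int):
        if read_length < 1:
            raise ValueError("read_length must be >= 1")
        self.model = model
        self.read_length = read_length
        self._by_chrom: dict[str, list[Transcript]] = {}
        for tx in model.transcripts():
            self._by_chrom.setdefault(tx.chrom, []).append(tx)
        self._unique_flags: dict[str, bool] = {}

    def compatible_genes(self, blocks: Sequence[GenomicInterval]) -> frozenset[str]:
        """Symbols of genes having a transcript window matching the blocks."""
        lo, hi = blocks[0].start, blocks[-1].end
        chrom = blocks[0].chrom
        out: set[str] = set()
        for tx in self._by_chrom.get(chrom, ()):
            if tx.gene_symbol in out:
                continue
            if tx.end < lo or tx.start > hi:
                continue
            if alignment_compatible(tx, blocks):
                out.add(tx.gene_symbol)
        return frozenset(out)

    def has_unique_window(self, symbol: str) -> bool:
        """Does the gene own >=1 read-length window compatible with it alone?"""
        cached = self._unique_flags.get(symbol)
        if cached is not None:
            return cached
        gene = self.model.genes[symbol]
        L = self.read_length
        found = False
        for tx in gene.transcripts:
            if tx.spliced_length < L:
                continue
            for offset in range(tx.spliced_length - L + 1):
                blocks = project_to_genome(tx, offset, L)
                if self.compatible_genes(blocks) == {symbol}:
                    found = True
                    break
            if found:
                break
        self._unique_flags[symbol] = found
        return found


def compatible_genes(alignment: Alignment, model: GeneModel) -> frozenset[str]:
    """Symbols of genes compatible with one alignment (convenience wrapper)."""
    return GeneAssigner(model, alignment.read_length).compatible_genes(alignment.blocks)


@dataclass
class CountTable:
    """Per-gene fractional read counts for one model and one sample."""

    model_name: str
    sample: str
    counts: dict[str, Fraction] = field(default_factory=dict)

    def add(self, symbol: str, amount: Fraction) -> None:
        self.counts[symbol] = self.counts.get(symbol, Fraction(0)) + amount

    def get(self, symbol: str) -> Fraction:
        return self.counts.get(symbol, Fraction(0))

    @property
    def total(self) -> Fraction:
        return sum(self.counts.values(), Fraction(0))

    def write_tsv(self, dest: IO[str] | str) -> None:
        if isinstance(dest, str):
            with open(dest, "w") as fh:
                self.write_tsv(fh)
            return
        dest.write("symbol\tcount\n")
        for symbol in sorted(self.counts):
            dest.write(f"{symbol}\t{float(self.counts[symbol]):.2f}\n")


def count_reads(
    unique_alignments: Iterable[Alignment],
    model: GeneModel,
    read_length: int,
    sample: str = "sample",
    assigner: GeneAssigner | None = None,
) -> CountTable:
    """Count uniquely placed reads into genes under the ambiguity rule.

    Every alignment must be a unique placement (ml = 1 upstream); multiple
    and unmapped reads are excluded before counting.
    """
    if assigner is None:
        assigner = GeneAssigner(model, read_length)
    table = CountTable(model.name, sample)
    # pre-register all model genes at zero so 'no expression' is explicit
    for symbol in model.genes:
        table.counts.setdefault(symbol, Fraction(0))
    seen: set[str] = set()
    for aln in unique_alignments:
        if aln.read_id in seen:
            raise ValueError(
                f"read {aln.read_id} appears twice: input must be unique placements"
            )
        seen.add(aln.read_id)
        genes = assigner.compatible_genes(aln.blocks)
        if not genes:
            continue
        if len(genes) == 1:
            table.add(next(iter(genes)), Fraction(1))
            continue
        unique_owners = sorted(g for g in genes if assigner.has_unique_window(g))
        targets = unique_owners if unique_owners else sorted(genes)
        share = Fraction(1, len(targets))
        for g in targets:
            table.add(g, share)
    return table


def ratio(c1: Fraction | float | int, c2: Fraction | float | int) -> Fraction:
    """Pseudocounted fold difference max(c1+1, c2+1) / min(c1+1, c2+1) >= 1."""
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    a = Fraction(c1) + 1
    b = Fraction(c2) + 1
    return max(a, b) / min(a, b)


@dataclass(frozen=True)
class ConcordanceRow:
    """Distribution of per-gene count ratios between two annotations.

    ``no_expr_pct``: both counts zero.  ``same_pct``: equal counts, not both
    zero (both-zero genes are counted only under NoExpr).  ``threshold_pcts``:
    cumulative percentage of common genes with ratio >= each threshold.
    """

    n_common: int
    no_expr_pct: float
    same_pct: float
    thresholds: tuple[float, ...]
    threshold_pcts: tuple[float, ...]

    def as_dict(self) -> dict:
        out = {
            "n_common": self.n_common,
            "NoExpr%": self.no_expr_pct,
            "Same%": self.same_pct,
        }
        for t, p in zip(self.thresholds, self.threshold_pcts):
            out[f">={t:g}%"] = p
        return out

    def write_tsv(self, dest: IO[str] | str) -> None:
        if isinstance(dest, str):
            with open(dest, "w") as fh:
                self.write_tsv(fh)
            return
        d = self.as_dict()
        dest.write("\t".join(d.keys()) + "\n")
        dest.write("\t".join(str(v) for v in d.values()) + "\n")


from ._utils import percent as _pct


def concordance_table(
    table_a: CountTable,
    table_b: CountTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ConcordanceRow:
    """Ratio-distribution row over the symbol intersection of two tables."""
    common = sorted(set(table_a.counts) & set(table_b.counts))
    if not common:
        raise ValueError("no common symbols between count tables")
    thresholds = tuple(sorted(thresholds))
    frac_thresholds = [Fraction(str(t)) for t in thresholds]
    n = len(common)
    n_noexpr = n_same = 0
    above = [0] * len(thresholds)
    for symbol in common:
        c1, c2 = table_a.get(symbol), table_b.get(symbol)
        if c1 == 0 and c2 == 0:
            n_noexpr += 1
            continue
        if c1 == c2:
            n_same += 1
        r = ratio(c1, c2)
        for i, t in enumerate(frac_thresholds):
            if r >= t:
                above[i] += 1
    return ConcordanceRow(
        n_common=n,
        no_expr_pct=_pct(n_noexpr, n),
        same_pct=_pct(n_same, n),
        thresholds=thresholds,
        threshold_pcts=tuple(_pct(a, n) for a in above),
    )


def log2_ratio(count_sample1: Fraction | float | int, count_sample2: Fraction | float | int) -> float:
    """log2((c1 + 1) / (c2 + 1)); pseudocount avoids division by zero."""
    if count_sample1 < 0 or count_sample2 < 0:
        raise ValueError("counts must be non-negative")
    return math.log2(float(Fraction(count_sample1) + 1) / float(Fraction(count_sample2) + 1))


@dataclass(frozen=True)
class DEConcordance:
    """Between-model agreement of per-gene fold changes (two samples)."""

    symbols: tuple[str, ...]
    log2_ratios_a: tuple[float, ...]
    log2_ratios_b: tuple[float, ...]
    n_diff_gt1: int
    n_diff_gt2: int
    n_diff_gt5: int

    def write_tsv(self, dest: IO[str] | str) -> None:
        if isinstance(dest, str):
            with open(dest, "w") as fh:
                self.write_tsv(fh)
            return
        dest.write("symbol\tlog2_ratio_model_a\tlog2_ratio_model_b\tabs_diff\n")
        for s, a, b in zip(self.symbols, self.log2_ratios_a, self.log2_ratios_b):
            dest.write(f"{s}\t{a:.4f}\t{b:.4f}\t{abs(a - b):.4f}\n")


def de_concordance(
    table_a_s1: CountTable,
    table_a_s2: CountTable,
    table_b_s1: CountTable,
    table_b_s2: CountTable,
) -> DEConcordance:
    """Per-gene log2 fold changes under each model and their disagreement."""
    common = (
        set(table_a_s1.counts)
        & set(table_a_s2.counts)
        & set(table_b_s1.counts)
        & set(table_b_s2.counts)
    )
    if not common:
        raise ValueError("no common symbols across the four count tables")
    symbols = tuple(sorted(common))
    la = tuple(log2_ratio(table_a_s1.get(s), table_a_s2.get(s)) for s in symbols)
    lb = tuple(log2_ratio(table_b_s1.get(s), table_b_s2.get(s)) for s in symbols)
    diffs = [abs(a - b) for a, b in zip(la, lb)]
    return DEConcordance(
        symbols=symbols,
        log2_ratios_a=la,
        log2_ratios_b=lb,
        n_diff_gt1=sum(d > 1 for d in diffs),
        n_diff_gt2=sum(d > 2 for d in diffs),
        n_diff_gt5=sum(d > 5 for d in diffs),
    )
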