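"""Structural comparison of gene models.

Covers symbol-set Venn decomposition across 2-3 annotations, per-gene
definition-difference classification between two models (identical exon
structure / differing span or exons / placed on a chromosome absent from the
genome), and within-model relations between exonically overlapping genes
(identical transcript sets, one gene nested with no read-length window of
its own, or plain partial overlap).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import IO, Sequence

from .annotation import Gene, GeneModel, GenomicInterval
from .quantify import GeneAssigner

__all__ = [
    "VennDecomposition",
    "GeneDiffRecord",
    "WithinModelRelation",
    "symbol_overlap",
    "cross_model_gene_diff",
    "model_diff_table",
    "within_model_relations",
]

CATEGORY_IDENTICAL = "identical"
CATEGORY_SPAN_OR_EXON = "span_or_exon_differs"
CATEGORY_ABSENT_CHROM = "absent_chromosome"
CATEGORY_MISSING = "missing_in_one_model"


@dataclass(frozen=True)
class VennDecomposition:
    """Disjoint membership-pattern regions of 2-3 models' symbol sets.

    Regions are keyed by the sorted tuple of model names containing the
    symbols; for three models there are 7 non-empty patterns.
    """

    model_names: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset[str]]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def common(self) -> frozenset[str]:
        """Symbols present in every model."""
        return self.regions.get(tuple(sorted(self.model_names)), frozenset())

    def to_json(self, dest: IO[str] | str) -> None:
        payload = {
            "models": list(self.model_names),
            "regions": {
                "&".join(k): sorted(v) for k, v in sorted(self.regions.items())
            },
            "counts": {"&".join(k): len(v) for k, v in sorted(self.regions.items())},
        }
        if isinstance(dest, str):
            with open(dest, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
        else:
            json.dump(payload, dest, indent=2, sort_keys=True)


def symbol_overlap(models: Sequence[GeneModel]) -> VennDecomposition:
    """Exact symbol-set decomposition by membership pattern."""
    if not 2 <= len(models) <= 3:
        raise ValueError(f"need 2 or 3 models, got {len(models)}")
    names = tuple(m.name for m in models)
    if len(set(names)) != len(names):
        raise ValueError("model names must be distinct")
    regions: dict[tuple[str, ...], set[str]] = {}
    all_symbols = set().union(*(m.symbols for m in models))
    for symbol in all_symbols:
        pattern = tuple(sorted(m.name for m in models if symbol in m.symbols))
        regions.setdefault(pattern, set()).add(symbol)
    return VennDecomposition(
        names, {k: frozenset(v) for k, v in regions.items()}
    )


@dataclass(frozen=True)
class GeneDiffRecord:
    symbol: str
    category: str
    span_a: GenomicInterval | None
    span_b: GenomicInterval | None
    n_transcripts_a: int
    n_transcripts_b: int


def _gene_span(gene: Gene) -> GenomicInterval | None:
    try:
        return gene.span()
    except ValueError:  # multi-chromosome gene: no single span
        return None


def cross_model_gene_diff(
    gene_in_a: Gene, gene_in_b: Gene, genome_chroms: set[str]
) -> GeneDiffRecord:
    """Classify how one symbol's definition differs between two models."""
    if gene_in_a.symbol != gene_in_b.symbol:
        raise ValueError(
            f"symbol mismatch: {gene_in_a.symbol!r} vs {gene_in_b.symbol!r}"
        )
    used = gene_in_a.chromosomes | gene_in_b.chromosomes
    if used - set(genome_chroms):
        category = CATEGORY_ABSENT_CHROM
    elif gene_in_a.structure_set() == gene_in_b.structure_set():
        category = CATEGORY_IDENTICAL
    else:
        category = CATEGORY_SPAN_OR_EXON
    return GeneDiffRecord(
        symbol=gene_in_a.symbol,
        category=category,
        span_a=_gene_span(gene_in_a),
        span_b=_gene_span(gene_in_b),
        n_transcripts_a=len(gene_in_a.transcripts),
        n_transcripts_b=len(gene_in_b.transcripts),
    )


def model_diff_table(
    model_a: GeneModel, model_b: GeneModel, genome_chroms: set[str]
) -> list[GeneDiffRecord]:
    """Per-symbol diff records over the union of both models' symbols."""
    records = []
    for symbol in sorted(model_a.symbols | model_b.symbols):
        in_a, in_b = symbol in model_a.genes, symbol in model_b.genes
        if in_a and in_b:
            records.append(
                cross_model_gene_diff(
                    model_a.genes[symbol], model_b.genes[symbol], genome_chroms
                )
            )
        else:
            gene = model_a.genes[symbol] if in_a else model_b.genes[symbol]
            records.append(
                GeneDiffRecord(
                    symbol=symbol,
                    category=CATEGORY_MISSING,
                    span_a=_gene_span(gene) if in_a else None,
                    span_b=_gene_span(gene) if in_b else None,
                    n_transcripts_a=len(gene.transcripts) if in_a else 0,
                    n_transcripts_b=len(gene.transcripts) if in_b else 0,
                )
            )
    return records


def write_diff_tsv(records: Sequence[GeneDiffRecord], dest: IO[str] | str) -> None:
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_diff_tsv(records, fh)
        return

    def fmt(span: GenomicInterval | None) -> str:
        return f"{span.chrom}:{span.start}-{span.end}" if span else "."

    dest.write("symbol\tcategory\tspan_a\tspan_b\tn_tx_a\tn_tx_b\n")
    for r in records:
        dest.write(
            f"{r.symbol}\t{r.category}\t{fmt(r.span_a)}\t{fmt(r.span_b)}\t"
            f"{r.n_transcripts_a}\t{r.n_transcripts_b}\n"
        )


@dataclass(frozen=True)
class WithinModelRelation:
    symbol_a: str
    symbol_b: str
    relation: str  # nested_no_unique_region | identical_transcripts | partial_overlap
    nested_symbols: tuple[str, ...] = ()  # genes lacking any unique window


def _exonic_overlap(gene_a: Gene, gene_b: Gene) -> bool:
    for ta in gene_a.transcripts:
        for tb in gene_b.transcripts:
            if ta.chrom != tb.chrom:
                continue
            for ea in ta.exons:
                for eb in tb.exons:
                    if ea.start <= eb.end and eb.start <= ea.end:
                        return True
    return False


def within_model_relations(
    model: GeneModel, read_length: int
) -> list[WithinModelRelation]:
    """Relations between every pair of exonically overlapping genes.

    A pair is ``identical_transcripts`` when the two genes' transcript
    structures coincide exactly; ``nested_no_unique_region`` when at least
    one of the genes has no read-length transcript window compatible with it
    alone (so it can never receive a unique read); otherwise
    ``partial_overlap``.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    assigner = GeneAssigner(model, read_length)
    out: list[WithinModelRelation] = []
    symbols = sorted(model.genes)
    for sym_a, sym_b in itertools.combinations(symbols, 2):
        gene_a, gene_b = model.genes[sym_a], model.genes[sym_b]
        if not _exonic_overlap(gene_a, gene_b):
            continue
        if gene_a.structure_set() == gene_b.structure_set():
            relation, nested = "identical_transcripts", ()
        else:
            lacking = tuple(
                s for s in (sym_a, sym_b) if not assigner.has_unique_window(s)
            )
            if lacking:
                relation, nested = "nested_no_unique_region", lacking
            else:
                relation, nested = "partial_overlap", ()
        out.append(WithinModelRelation(sym_a, sym_b, relation, nested))
    return out
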