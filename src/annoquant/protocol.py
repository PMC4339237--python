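"""Two-stage mapping protocol and read reclassification.

Stage 1 keeps only reads that map to the spliced transcriptome at all (reads
the annotation does not cover tell us nothing about the annotation's role in
mapping).  Stage 2 remaps the survivors with and without the gene model and
reclassifies every read that was *uniquely* mapped in transcriptome-only
mode into one of four fates when the model is withheld:

* identical   — same chromosome, strand and exact block coordinates
                (splice sites included);
* alternative — still uniquely mapped, but placed differently; a junction
                read re-placed contiguously over the same span is
                alternative, not identical;
* multiple    — became a multi-mapping read;
* unmapped    — no placement at all without the model.

Summaries are stratified by junction status of the with-model alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

from .annotation import GeneModel, Genome
from ._utils import percent
from .mapper import (
    Alignment,
    MappingResult,
    SpliceParams,
    DEFAULT_SPLICE,
    get_transcriptome_mapper,
    ml_status,
)

__all__ = [
    "ReadClassification",
    "StratifiedSummary",
    "MappingSummary",
    "Stage1Result",
    "stage1_filter",
    "classify_read",
    "stratified_summary",
    "mapping_summary",
    "truth_recovery",
    "CATEGORIES",
]

CATEGORIES = ("identical", "alternative", "multiple", "unmapped")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    category: str
    is_junction: bool


@dataclass(frozen=True)
class Stage1Result:
    """Reads retained by stage 1 plus their transcriptome mapping results."""

    retained: tuple[tuple[str, str], ...]
    dropped: tuple[str, ...]
    results: Mapping[str, MappingResult]

    @property
    def retained_fraction(self) -> float:
        total = len(self.retained) + len(self.dropped)
        return len(self.retained) / total if total else 0.0


def stage1_filter(
    reads: Sequence[tuple[str, str]],
    model: GeneModel,
    genome: Genome,
    max_mismatch: int,
) -> Stage1Result:
    """Keep exactly the reads with #ML >= 1 under transcriptome-only mapping."""
    mapper = get_transcriptome_mapper(model, genome)
    retained: list[tuple[str, str]] = []
    dropped: list[str] = []
    results: dict[str, MappingResult] = {}
    for read_id, seq in reads:
        res = mapper.map(read_id, seq, max_mismatch)
        results[read_id] = res
        if res.ml >= 1:
            retained.append((read_id, seq))
        else:
            dropped.append(read_id)
    return Stage1Result(tuple(retained), tuple(dropped), results)


def classify_read(
    with_model: MappingResult, without_model: MappingResult
) -> ReadClassification:
    """Four-fate classification of a with-model uniquely mapped read."""
    if with_model.ml != 1:
        raise ValueError(
            f"classification is defined only for uniquely mapped reads "
            f"(read {with_model.read_id} has #ML={with_model.ml})"
        )
    ref = with_model.best
    if without_model.ml == 0:
        category = "unmapped"
    elif without_model.ml >= 2:
        category = "multiple"
    elif without_model.best.same_placement(ref):
        category = "identical"
    else:
        category = "alternative"
    return ReadClassification(with_model.read_id, category, ref.is_junction)


@dataclass(frozen=True)
class StratifiedSummary:
    """Category percentages per junction stratum plus the junction fraction."""

    n_total: int
    n_junction: int
    junction_pcts: dict[str, float]
    non_junction_pcts: dict[str, float]

    @property
    def junction_fraction(self) -> float:
        return self.n_junction / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_junction": self.n_junction,
            "junction_fraction": self.junction_fraction,
            "junction": self.junction_pcts,
            "non_junction": self.non_junction_pcts,
        }


def _category_pcts(items: Sequence[ReadClassification]) -> dict[str, float]:
    if not items:
        return {c: 0.0 for c in CATEGORIES}
    return {
        c: percent(sum(1 for x in items if x.category == c), len(items))
        for c in CATEGORIES
    }


def stratified_summary(
    classifications: Sequence[ReadClassification],
) -> StratifiedSummary:
    if not classifications:
        raise ValueError("no classifications to summarize")
    junction = [c for c in classifications if c.is_junction]
    non_junction = [c for c in classifications if not c.is_junction]
    return StratifiedSummary(
        n_total=len(classifications),
        n_junction=len(junction),
        junction_pcts=_category_pcts(junction),
        non_junction_pcts=_category_pcts(non_junction),
    )


@dataclass(frozen=True)
class MappingSummary:
    """Per-mode unmapped/unique/multiple percentages."""

    per_mode: dict[str, dict[str, float]]
    n_per_mode: dict[str, int]

    def as_dict(self) -> dict:
        return {
            mode: {"n": self.n_per_mode[mode], **pcts}
            for mode, pcts in self.per_mode.items()
        }


def mapping_summary(
    results_by_mode: Mapping[str, Sequence[MappingResult]],
) -> MappingSummary:
    per_mode: dict[str, dict[str, float]] = {}
    n_per_mode: dict[str, int] = {}
    for mode, results in results_by_mode.items():
        if not results:
            raise ValueError(f"empty result group for mode {mode!r}")
        statuses = [ml_status(r) for r in results]
        n = len(statuses)
        per_mode[mode] = {
            s: percent(statuses.count(s), n) for s in ("unmapped", "unique", "multiple")
        }
        n_per_mode[mode] = n
    return MappingSummary(per_mode, n_per_mode)


def truth_recovery(
    alignments: Mapping[str, Alignment],
    truth_keys: Mapping[str, tuple],
) -> float:
    """Fraction of uniquely placed reads whose placement equals the simulated
    origin, compared on (chromosome, strand, exact block coordinates).

    `truth_keys` maps read id -> (chrom, strand, ((start, end), ...)), the
    same shape as ``Alignment.placement_key()``.
    """
    if not alignments:
        raise ValueError("no alignments to score")
    n_correct = 0
    for read_id, aln in alignments.items():
        if read_id not in truth_keys:
            raise KeyError(f"no truth record for read {read_id}")
        if aln.placement_key() == truth_keys[read_id]:
            n_correct += 1
    return n_correct / len(alignments)


def write_classification_tsv(
    classifications: Iterable[ReadClassification], dest: IO[str] | str
) -> None:
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_classification_tsv(classifications, fh)
        return
    dest.write("read_id\tcategory\tis_junction\n")
    for c in classifications:
        dest.write(f"{c.read_id}\t{c.category}\t{int(c.is_junction)}\n")
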