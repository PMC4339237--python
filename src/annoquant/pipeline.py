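"""End-to-end orchestration: simulate -> stage 1 -> stage 2 -> classify ->
quantify -> concordance, writing a deterministic report bundle."""

from __future__ import annotations

import json
import os
import sys
from dataclasses import dataclass, field
from fractions import Fraction
from typing import IO, Sequence

import numpy as np
import yaml

from . import model_compare, protocol, quantify
from .annotation import (
    GeneModel,
    Genome,
    parse_gtf,
    read_fasta,
    write_fasta,
    write_gtf,
)
from .mapper import (
    MODE_NONE,
    MODE_SEQUENTIAL,
    MODE_TRANSCRIPTOME,
    SpliceParams,
    default_max_mismatch,
    get_genome_mapper,
    get_transcriptome_mapper,
    map_sequential,
    write_sam,
)
from .synthetic_data import (
    ArchetypeSpec,
    generate_annotation_pair,
    generate_genome,
    read_fastq,
    simulate_reads,
    write_fastq,
    write_truth_tsv,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # either provide paths ...
    genome_fasta: str | None = None
    model_a_gtf: str | None = None
    model_b_gtf: str | None = None
    reads_fastq: str | None = None
    # ... or a simulation spec
    simulate: bool = True
    archetypes: Sequence[str] = (
        "identical",
        "three_prime_extension",
        "nested_gene_vs_shared_transcript",
        "absent_chromosome",
        "model_unique_gene",
        "processed_retrocopy",
    )
    chrom_lengths: Sequence[int] = (200_000, 150_000)
    n_genes: int = 24
    n_reads: int = 10_000
    n_samples: int = 2
    read_length: int = 75
    error_rate: float = 0.002
    max_mismatch: int | None = None
    min_anchor: int = 10
    min_intron: int = 20
    max_intron: int = 10_000
    thresholds: Sequence[float] = quantify.DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        if not self.simulate:
            for label, path in (
                ("genome_fasta", self.genome_fasta),
                ("model_a_gtf", self.model_a_gtf),
                ("model_b_gtf", self.model_b_gtf),
                ("reads_fastq", self.reads_fastq),
            ):
                if not path or not os.path.exists(path):
                    raise ValueError(f"{label} missing or nonexistent: {path!r}")

    @property
    def effective_max_mismatch(self) -> int:
        if self.max_mismatch is not None:
            return self.max_mismatch
        return default_max_mismatch(self.read_length)

    @property
    def splice(self) -> SpliceParams:
        return SpliceParams(self.min_anchor, self.min_intron, self.max_intron)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulate": self.simulate,
            "archetypes": list(self.archetypes),
            "chrom_lengths": list(self.chrom_lengths),
            "n_genes": self.n_genes,
            "n_reads": self.n_reads,
            "n_samples": self.n_samples,
            "read_length": self.read_length,
            "error_rate": self.error_rate,
            "max_mismatch": self.effective_max_mismatch,
            "min_anchor": self.min_anchor,
            "min_intron": self.min_intron,
            "max_intron": self.max_intron,
            "thresholds": list(self.thresholds),
            "genome_fasta": self.genome_fasta,
            "model_a_gtf": self.model_a_gtf,
            "model_b_gtf": self.model_b_gtf,
            "reads_fastq": self.reads_fastq,
        }


def build_archetype_specs(archetypes: Sequence[str], n_genes: int) -> list[ArchetypeSpec]:
    """Pad the requested archetypes with 'identical' filler genes up to n_genes."""
    specs = [ArchetypeSpec(a) for a in archetypes]
    while len(specs) < n_genes:
        specs.append(ArchetypeSpec("identical"))
    return specs


def sample_weights(model: GeneModel, seed: int, sample_index: int) -> dict[str, float]:
    """Tissue-like per-gene expression weights (log-normal), per sample."""
    ss = np.random.SeedSequence(seed).spawn(10 + sample_index)[-1]
    rng = np.random.default_rng(ss)
    return {
        symbol: float(rng.lognormal(mean=0.0, sigma=1.0))
        for symbol in sorted(model.genes)
    }


def _log(stream: IO[str], log_lines: list[str], message: str) -> None:
    stream.write(message + "\n")
    log_lines.append(message)


def run_pipeline(config: PipelineConfig, log_stream: IO[str] | None = None) -> dict:
    """Run every stage and write the report bundle into config.out_dir."""
    log_stream = log_stream or sys.stderr
    log: list[str] = []
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    bundle: dict = {"out_dir": out}

    def stage(name):
        _log(log_stream, log, f"[stage] {name}")

    try:
        stage("inputs")
        if config.simulate:
            genome = generate_genome(config.chrom_lengths, config.seed)
            specs = build_archetype_specs(config.archetypes, config.n_genes)
            model_a, model_b, archetype_truth = generate_annotation_pair(
                genome, specs, config.seed
            )
            samples = {}
            for s in range(1, config.n_samples + 1):
                weights = sample_weights(model_a, config.seed, s)
                reads, truths = simulate_reads(
                    genome,
                    model_a,
                    weights,
                    config.n_reads,
                    config.read_length,
                    config.error_rate,
                    config.seed + s,
                )
                samples[f"s{s}"] = (reads, truths)
            write_fasta(genome, os.path.join(out, "genome.fa"))
            write_gtf(model_a, os.path.join(out, "model_a.gtf"))
            write_gtf(model_b, os.path.join(out, "model_b.gtf"))
            with open(os.path.join(out, "archetype_truth.tsv"), "w") as fh:
                fh.write("symbol\tarchetype\tchrom\n")
                for row in archetype_truth:
                    fh.write(f"{row['symbol']}\t{row['archetype']}\t{row['chrom']}\n")
            for name, (reads, truths) in samples.items():
                write_fastq(reads, os.path.join(out, f"reads_{name}.fastq"))
                write_truth_tsv(truths, os.path.join(out, f"truth_{name}.tsv"))
        else:
            genome = read_fasta(config.genome_fasta)
            model_a = parse_gtf(config.model_a_gtf, name="model_a")
            model_b = parse_gtf(config.model_b_gtf, name="model_b")
            samples = {"s1": (read_fastq(config.reads_fastq), None)}

        mm = config.effective_max_mismatch
        splice = config.splice
        ref_lengths = {c: genome.length_of(c) for c in genome.keys()}

        stage("model_compare")
        venn = model_compare.symbol_overlap([model_a, model_b])
        venn.to_json(os.path.join(out, "venn.json"))
        diff = model_compare.model_diff_table(model_a, model_b, set(genome.keys()))
        model_compare.write_diff_tsv(diff, os.path.join(out, "gene_diff.tsv"))
        for model in (model_a, model_b):
            relations = model_compare.within_model_relations(model, config.read_length)
            with open(os.path.join(out, f"relations_{model.name}.tsv"), "w") as fh:
                fh.write("symbol_a\tsymbol_b\trelation\tnested_symbols\n")
                for r in relations:
                    fh.write(
                        f"{r.symbol_a}\t{r.symbol_b}\t{r.relation}\t"
                        f"{','.join(r.nested_symbols)}\n"
                    )

        # per-sample mapping, classification and counting
        count_tables: dict[tuple[str, str], quantify.CountTable] = {}
        assigners = {
            model.name: quantify.GeneAssigner(model, config.read_length)
            for model in (model_a, model_b)
        }
        for sample_name, (reads, _truths) in samples.items():
            stage(f"stage1 [{sample_name}]")
            s1 = protocol.stage1_filter(reads, model_a, genome, mm)
            _log(
                log_stream,
                log,
                f"  {sample_name}: {len(s1.retained)}/{len(reads)} reads retained",
            )
            write_fastq(s1.retained, os.path.join(out, f"stage1_{sample_name}.fastq"))

            stage(f"stage2 mapping [{sample_name}]")
            tx_mapper = get_transcriptome_mapper(model_a, genome)
            ge_mapper = get_genome_mapper(genome)
            with_model = [s1.results[rid] for rid, _ in s1.retained]
            without_model = [
                ge_mapper.map(rid, seq, mm, splice) for rid, seq in s1.retained
            ]
            sequential = [
                map_sequential((rid, seq), model_a, genome, mm, splice)
                for rid, seq in s1.retained
            ]
            summary = protocol.mapping_summary(
                {
                    MODE_TRANSCRIPTOME: with_model,
                    MODE_NONE: without_model,
                    MODE_SEQUENTIAL: sequential,
                }
            )
            with open(os.path.join(out, f"mapping_summary_{sample_name}.json"), "w") as fh:
                json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
            seqs = dict(s1.retained)
            write_sam(
                with_model,
                ref_lengths,
                os.path.join(out, f"with_model_{sample_name}.sam"),
                seqs,
            )
            write_sam(
                without_model,
                ref_lengths,
                os.path.join(out, f"without_model_{sample_name}.sam"),
                seqs,
            )

            stage(f"classification [{sample_name}]")
            without_by_id = {r.read_id: r for r in without_model}
            classifications = [
                protocol.classify_read(res, without_by_id[res.read_id])
                for res in with_model
                if res.ml == 1
            ]
            protocol.write_classification_tsv(
                classifications, os.path.join(out, f"classification_{sample_name}.tsv")
            )
            if classifications:
                strat = protocol.stratified_summary(classifications)
                with open(
                    os.path.join(out, f"stratified_summary_{sample_name}.json"), "w"
                ) as fh:
                    json.dump(strat.as_dict(), fh, indent=2, sort_keys=True)

            stage(f"quantify [{sample_name}]")
            for model in (model_a, model_b):
                mapper = get_transcriptome_mapper(model, genome)
                unique = [
                    res.best
                    for res in (mapper.map(rid, seq, mm) for rid, seq in reads)
                    if res.ml == 1
                ]
                table = quantify.count_reads(
                    unique,
                    model,
                    config.read_length,
                    sample=sample_name,
                    assigner=assigners[model.name],
                )
                table.write_tsv(
                    os.path.join(out, f"counts_{model.name}_{sample_name}.tsv")
                )
                count_tables[(model.name, sample_name)] = table
                _log(
                    log_stream,
                    log,
                    f"  {model.name}/{sample_name}: {len(unique)} unique reads, "
                    f"total count {float(table.total):.2f}",
                )

        stage("concordance")
        first_sample = next(iter(samples))
        row = quantify.concordance_table(
            count_tables[("model_a", first_sample)],
            count_tables[("model_b", first_sample)],
            config.thresholds,
        )
        row.write_tsv(os.path.join(out, "concordance.tsv"))
        bundle["concordance"] = row

        if len(samples) >= 2:
            stage("de_concordance")
            names = list(samples)
            de = quantify.de_concordance(
                count_tables[("model_a", names[0])],
                count_tables[("model_a", names[1])],
                count_tables[("model_b", names[0])],
                count_tables[("model_b", names[1])],
            )
            de.write_tsv(os.path.join(out, "de_concordance.tsv"))
            with open(os.path.join(out, "de_summary.json"), "w") as fh:
                json.dump(
                    {
                        "n_genes": len(de.symbols),
                        "n_abs_diff_gt1": de.n_diff_gt1,
                        "n_abs_diff_gt2": de.n_diff_gt2,
                        "n_abs_diff_gt5": de.n_diff_gt5,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            bundle["de_concordance"] = de

        with open(os.path.join(out, "effective_config.json"), "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        with open(os.path.join(out, "run_log.txt"), "w") as fh:
            fh.write("\n".join(log) + "\n")
        bundle["log"] = log
        return bundle
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context added
        failed = log[-1] if log else "startup"
        raise PipelineError(f"pipeline failed at {failed!r}: {exc}") from exc
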