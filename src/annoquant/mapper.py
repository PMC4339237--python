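"""Deterministic toy read mapper: exact/k-mismatch, splice-aware at the genome.

Three modes are exposed:

* ``map_to_transcriptome`` — scan spliced transcript sequences, project hits
  to genomic blocks, collapse isoform-duplicate placements.
* ``map_to_genome`` — contiguous placements plus two-segment spliced
  placements found de novo (one junction per read, anchored segments, intron
  size bounds).  Contiguous placements beat spliced ones at equal mismatch
  count.
* ``map_sequential`` — transcriptome first, genome only for the leftovers.

The search is seed-and-verify: with at most ``m`` mismatches and ``m + 1``
disjoint exact seeds, at least one seed is error-free (pigeonhole); for the
spliced search one extra seed covers the junction crossing.  Candidate
placements are then verified with vectorized mismatch counts, keeping only
the minimal-mismatch stratum.  No indels, no soft clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .annotation import (
    Gene,
    GeneModel,
    Genome,
    GenomicInterval,
    Transcript,
    build_transcriptome,
    project_to_genome,
    reverse_complement,
)

__all__ = [
    "Alignment",
    "MappingResult",
    "SpliceParams",
    "TranscriptomeMapper",
    "GenomeMapper",
    "map_to_transcriptome",
    "map_to_genome",
    "map_sequential",
    "ml_status",
    "write_sam",
    "read_sam",
    "DEFAULT_SPLICE",
    "default_max_mismatch",
]

MODE_TRANSCRIPTOME = "transcriptome_only"
MODE_SEQUENTIAL = "transcriptome_plus_genome"
MODE_NONE = "none"


@dataclass(frozen=True)
class SpliceParams:
    """De-novo splice search bounds for genome-mode mapping."""

    min_anchor: int = 10
    min_intron: int = 20
    max_intron: int = 10_000

    def __post_init__(self) -> None:
        if self.min_anchor < 1 or self.min_intron < 1:
            raise ValueError("splice parameters must be positive")
        if self.min_intron > self.max_intron:
            raise ValueError("min_intron > max_intron")


DEFAULT_SPLICE = SpliceParams()


def default_max_mismatch(read_length: int) -> int:
    """2 mismatches for 75 bp reads, 1 for 50 bp and shorter."""
    return 1 if read_length <= 50 else 2


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]
    mismatches: int

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end >= b.start:
                raise ValueError("alignment blocks must be ascending, disjoint")

    @property
    def is_junction(self) -> bool:
        return len(self.blocks) >= 2

    @property
    def read_length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    def placement_key(self) -> tuple:
        """Genomic identity: chromosome, strand, exact block coordinates."""
        return (
            self.chrom,
            self.strand,
            tuple((b.start, b.end) for b in self.blocks),
        )

    def same_placement(self, other: "Alignment") -> bool:
        return self.placement_key() == other.placement_key()


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    mode: str
    alignments: tuple[Alignment, ...]

    @property
    def ml(self) -> int:
        return len(self.alignments)

    @property
    def best(self) -> Alignment:
        if not self.alignments:
            raise ValueError(f"read {self.read_id} is unmapped")
        return self.alignments[0]


def ml_status(result: MappingResult) -> str:
    """'unmapped' (#ML = 0), 'unique' (#ML = 1) or 'multiple' (#ML >= 2)."""
    if result.ml == 0:
        return "unmapped"
    if result.ml == 1:
        return "unique"
    return "multiple"


# ---------------------------------------------------------------------------
# encoding helpers


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _seed_offsets(length: int, n_seeds: int) -> tuple[int, list[int]] | None:
    """Disjoint seed layout: seed length and start offsets, or None if the
    read is too short to carry n_seeds informative seeds."""
    k = min(16, length // n_seeds)
    if k < 4:
        return None
    step = length // n_seeds
    return k, [i * step for i in range(n_seeds)]


def _collapse(alignments: Iterable[Alignment]) -> tuple[Alignment, ...]:
    """Keep the minimal-mismatch stratum; collapse identical placements;
    canonical order (chrom, start, strand)."""
    best: dict[tuple, Alignment] = {}
    for aln in alignments:
        key = aln.placement_key()
        kept = best.get(key)
        if kept is None or aln.mismatches < kept.mismatches:
            best[key] = aln
    if not best:
        return ()
    min_mm = min(a.mismatches for a in best.values())
    stratum = [a for a in best.values() if a.mismatches == min_mm]
    stratum.sort(key=lambda a: (a.chrom, a.start, a.strand, a.end))
    return tuple(stratum)


class _KmerIndex:
    """Exact k-mer -> start positions over a list of sequences."""

    def __init__(self, seqs: Sequence[str]):
        self._seqs = seqs
        self._by_k: dict[int, list[dict[bytes, list[int]]]] = {}

    def lookup(self, k: int, seq_idx: int, kmer: bytes) -> list[int]:
        if k not in self._by_k:
            tables = []
            for s in self._seqs:
                table: dict[bytes, list[int]] = {}
                raw = s.encode("ascii")
                for i in range(len(raw) - k + 1):
                    table.setdefault(raw[i : i + k], []).append(i)
                tables.append(table)
            self._by_k[k] = tables
        return self._by_k[k][seq_idx].get(kmer, [])


# ---------------------------------------------------------------------------
# transcriptome mapping


class TranscriptomeMapper:
    """Maps reads against the spliced transcriptome of one model + genome."""

    def __init__(self, model: GeneModel, genome: Genome, warn_stream: IO[str] | None = None):
        self.model = model
        self.genome = genome
        self.genome_version = genome.version
        self.entries = build_transcriptome(genome, model, warn_stream)
        self._arrays = [_encode(seq) for _, seq in self.entries]
        self._index = _KmerIndex([seq for _, seq in self.entries])

    def _candidates(self, read_arr: np.ndarray, raw: bytes, max_mm: int) -> set[tuple[int, int]]:
        """(transcript_idx, offset) candidates via pigeonhole seeding."""
        L = len(raw)
        layout = _seed_offsets(L, max_mm + 1)
        cands: set[tuple[int, int]] = set()
        if layout is None:
            # read too short for seeding: brute scan (toy-scale fallback)
            for ti, arr in enumerate(self._arrays):
                for off in range(len(arr) - L + 1):
                    cands.add((ti, off))
            return cands
        k, offsets = layout
        for ti in range(len(self._arrays)):
            tlen = len(self._arrays[ti])
            for soff in offsets:
                for pos in self._index.lookup(k, ti, raw[soff : soff + k]):
                    start = pos - soff
                    if 0 <= start and start + L <= tlen:
                        cands.add((ti, start))
        return cands

    def map(self, read_id: str, seq: str, max_mismatch: int) -> MappingResult:
        if not seq:
            raise ValueError("empty read")
        seq = seq.upper()
        hits: list[Alignment] = []
        for oriented, flipped in ((seq, False), (reverse_complement(seq), True)):
            raw = oriented.encode("ascii")
            arr = _encode(oriented)
            L = len(arr)
            for ti, off in self._candidates(arr, raw, max_mismatch):
                mm = int(np.count_nonzero(self._arrays[ti][off : off + L] != arr))
                if mm > max_mismatch:
                    continue
                tx = self.entries[ti][0]
                blocks = project_to_genome(tx, off, L)
                strand = tx.strand
                if flipped:
                    strand = "-" if strand == "+" else "+"
                hits.append(Alignment(read_id, tx.chrom, strand, blocks, mm))
        return MappingResult(read_id, MODE_TRANSCRIPTOME, _collapse(hits))


# ---------------------------------------------------------------------------
# genome mapping


class GenomeMapper:
    """Maps reads directly against genomic sequence, with de-novo two-segment
    spliced placements."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self.genome_version = genome.version
        self.chroms = sorted(genome.keys())
        self._arrays = {c: _encode(genome[c]) for c in self.chroms}
        self._index = _KmerIndex([genome[c] for c in self.chroms])

    def _contiguous(
        self, read_id: str, arr: np.ndarray, raw: bytes, strand: str, max_mm: int
    ) -> list[Alignment]:
        L = len(arr)
        layout = _seed_offsets(L, max_mm + 1)
        hits: list[Alignment] = []
        for ci, chrom in enumerate(self.chroms):
            garr = self._arrays[chrom]
            n = len(garr)
            if layout is None:
                starts: Iterable[int] = range(max(0, n - L + 1))
            else:
                k, offsets = layout
                cand: set[int] = set()
                for soff in offsets:
                    for pos in self._index.lookup(k, ci, raw[soff : soff + k]):
                        start = pos - soff
                        if 0 <= start and start + L <= n:
                            cand.add(start)
                starts = cand
            for start in starts:
                mm = int(np.count_nonzero(garr[start : start + L] != arr))
                if mm <= max_mm:
                    hits.append(
                        Alignment(
                            read_id,
                            chrom,
                            strand,
                            (GenomicInterval(chrom, start + 1, start + L, strand),),
                            mm,
                        )
                    )
        return hits

    @staticmethod
    def _contig_mis_from(garr: np.ndarray, arr: np.ndarray, start: int) -> np.ndarray:
        """Mismatch vector of the read laid contiguously from `start`;
        out-of-range genome positions count as mismatches."""
        L = len(arr)
        n = len(garr)
        mis = np.ones(L, dtype=np.int64)
        lo = max(0, start)
        hi = min(n, start + L)
        if hi > lo:
            mis[lo - start : hi - start] = garr[lo:hi] != arr[lo - start : hi - start]
        return mis

    def _emit_splits(
        self,
        hits: list[Alignment],
        read_id: str,
        chrom: str,
        strand: str,
        l: int,
        e: int,
        left_cum: np.ndarray,
        right_cum: np.ndarray,
        max_mm: int,
        smin: int,
        smax: int,
        L: int,
    ) -> None:
        right_total = right_cum[L]
        splits = np.arange(smin, smax + 1)
        mm_by_split = left_cum[splits] + right_total - right_cum[splits]
        for s in splits[mm_by_split <= max_mm]:
            s = int(s)
            mm = int(left_cum[s] + right_total - right_cum[s])
            blocks = (
                GenomicInterval(chrom, l + 1, l + s, strand),
                GenomicInterval(chrom, e - (L - s) + 2, e + 1, strand),
            )
            hits.append(Alignment(read_id, chrom, strand, blocks, mm))

    def _spliced(
        self,
        read_id: str,
        arr: np.ndarray,
        raw: bytes,
        strand: str,
        max_mm: int,
        splice: SpliceParams,
    ) -> list[Alignment]:
        """Two-segment placements.  Any valid placement has, by pigeonhole
        over max_mm + 2 disjoint seeds, at least one error-free seed fully
        inside one segment; that seed fixes that segment's genomic position
        and the opposite segment is then found by a windowed scan over the
        allowed intron range (anchor prefilter, then exact split evaluation).
        """
        L = len(arr)
        if L < 2 * splice.min_anchor:
            return []
        layout = _seed_offsets(L, max_mm + 2)
        hits: list[Alignment] = []
        smin, smax = splice.min_anchor, L - splice.min_anchor
        ma = splice.min_anchor
        for ci, chrom in enumerate(self.chroms):
            garr = self._arrays[chrom]
            n = len(garr)
            lefts: set[int] = set()
            rights: set[int] = set()  # 0-based genomic position of the read's last base
            if layout is None:
                lefts = set(range(n))
            else:
                k, offsets = layout
                for soff in offsets:
                    for pos in self._index.lookup(k, ci, raw[soff : soff + k]):
                        lefts.add(pos - soff)
                        rights.add(pos + (L - soff) - 1)
            win = sliding_window_view(garr, ma) if n >= ma else None
            for l in sorted(lefts):
                if l < 0 or l + smin > n or win is None:
                    continue
                left_cum = np.concatenate(
                    ([0], np.cumsum(self._contig_mis_from(garr, arr, l)))
                )
                if int(left_cum[smin : smax + 1].min()) > max_mm:
                    continue
                # window of allowed read-end positions e (gap = e - l - L + 1)
                vlo = l + L - 1 + splice.min_intron
                vhi = min(l + L - 1 + splice.max_intron, n - 1)
                if vlo > vhi:
                    continue
                # anchor prefilter: last min_anchor read bases ending at e
                starts = np.arange(vlo - ma + 1, vhi - ma + 2)
                anchor_mm = (win[starts] != arr[L - ma :]).sum(axis=1)
                for e in starts[anchor_mm <= max_mm] + ma - 1:
                    e = int(e)
                    right_cum = np.concatenate(
                        ([0], np.cumsum(self._contig_mis_from(garr, arr, e - L + 1)))
                    )
                    self._emit_splits(
                        hits, read_id, chrom, strand, l, e, left_cum, right_cum,
                        max_mm, smin, smax, L,
                    )
            for e in sorted(rights):
                if e >= n or e - smin + 1 < 0 or win is None:
                    continue
                right_cum = np.concatenate(
                    ([0], np.cumsum(self._contig_mis_from(garr, arr, e - L + 1)))
                )
                right_total = right_cum[L]
                if int((right_total - right_cum[smin : smax + 1]).min()) > max_mm:
                    continue
                vhi_l = min(e - L + 1 - splice.min_intron, n - ma)
                vlo_l = max(0, e - L + 1 - splice.max_intron)
                if vlo_l > vhi_l:
                    continue
                starts = np.arange(vlo_l, vhi_l + 1)
                anchor_mm = (win[starts] != arr[:ma]).sum(axis=1)
                for l in starts[anchor_mm <= max_mm]:
                    l = int(l)
                    left_cum = np.concatenate(
                        ([0], np.cumsum(self._contig_mis_from(garr, arr, l)))
                    )
                    self._emit_splits(
                        hits, read_id, chrom, strand, l, e, left_cum, right_cum,
                        max_mm, smin, smax, L,
                    )
        return hits

    def map(
        self,
        read_id: str,
        seq: str,
        max_mismatch: int,
        splice: SpliceParams = DEFAULT_SPLICE,
    ) -> MappingResult:
        if not seq:
            raise ValueError("empty read")
        seq = seq.upper()
        oriented = ((seq, "+"), (reverse_complement(seq), "-"))
        contig: list[Alignment] = []
        for s, strand in oriented:
            contig.extend(
                self._contiguous(read_id, _encode(s), s.encode("ascii"), strand, max_mismatch)
            )
        best_contig = min((a.mismatches for a in contig), default=max_mismatch + 1)
        # spliced placements survive only with strictly fewer mismatches than
        # the best contiguous one (contiguous-beats-spliced tie-break)
        spliced_budget = min(max_mismatch, best_contig - 1)
        spliced: list[Alignment] = []
        if spliced_budget >= 0:
            for s, strand in oriented:
                spliced.extend(
                    self._spliced(
                        read_id, _encode(s), s.encode("ascii"), strand, spliced_budget, splice
                    )
                )
        return MappingResult(read_id, MODE_NONE, _collapse(contig + spliced))


# ---------------------------------------------------------------------------
# functional façade with engine memoisation

_TX_CACHE: dict[tuple[int, int, int], TranscriptomeMapper] = {}
_GE_CACHE: dict[tuple[int, int], GenomeMapper] = {}


def get_transcriptome_mapper(model: GeneModel, genome: Genome) -> TranscriptomeMapper:
    key = (id(model), id(genome), genome.version)
    mapper = _TX_CACHE.get(key)
    if mapper is None:
        _TX_CACHE.clear()
        mapper = TranscriptomeMapper(model, genome)
        _TX_CACHE[key] = mapper
    return mapper


def get_genome_mapper(genome: Genome) -> GenomeMapper:
    key = (id(genome), genome.version)
    mapper = _GE_CACHE.get(key)
    if mapper is None:
        _GE_CACHE.clear()
        mapper = GenomeMapper(genome)
        _GE_CACHE[key] = mapper
    return mapper


def map_to_transcriptome(
    read: tuple[str, str], model: GeneModel, genome: Genome, max_mismatch: int
) -> MappingResult:
    """Map one (read_id, sequence) pair in transcriptome-only mode."""
    read_id, seq = read
    return get_transcriptome_mapper(model, genome).map(read_id, seq, max_mismatch)


def map_to_genome(
    read: tuple[str, str],
    genome: Genome,
    max_mismatch: int,
    splice: SpliceParams = DEFAULT_SPLICE,
) -> MappingResult:
    """Map one (read_id, sequence) pair directly to the genome."""
    read_id, seq = read
    return get_genome_mapper(genome).map(read_id, seq, max_mismatch, splice)


def map_sequential(
    read: tuple[str, str],
    model: GeneModel,
    genome: Genome,
    max_mismatch: int,
    splice: SpliceParams = DEFAULT_SPLICE,
) -> MappingResult:
    """Transcriptome first; unmapped reads fall through to the genome."""
    first = map_to_transcriptome(read, model, genome, max_mismatch)
    if first.ml >= 1:
        return MappingResult(first.read_id, MODE_SEQUENTIAL, first.alignments)
    second = map_to_genome(read, genome, max_mismatch, splice)
    return MappingResult(second.read_id, MODE_SEQUENTIAL, second.alignments)


# ---------------------------------------------------------------------------
# SAM I/O (text dialect: M/N CIGAR only, XO = mode tag, NM = mismatches)


def _cigar(blocks: tuple[GenomicInterval, ...]) -> str:
    parts = []
    for i, b in enumerate(blocks):
        if i:
            gap = b.start - blocks[i - 1].end - 1
            parts.append(f"{gap}N")
        parts.append(f"{b.length}M")
    return "".join(parts)


def write_sam(
    results: Iterable[MappingResult],
    ref_lengths: dict[str, int],
    dest: IO[str] | str,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write mapping results as SAM text.

    One record per alignment (secondary flag past the first); unmapped reads
    get a single flag-4 record.  Spliced blocks use M/N CIGAR runs; the mode
    is stored in the XO tag and the mismatch count in NM.
    """
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_sam(results, ref_lengths, fh, sequences)
        return
    dest.write("@HD\tVN:1.6\tSO:unknown\n")
    for name in sorted(ref_lengths):
        dest.write(f"@SQ\tSN:{name}\tLN:{ref_lengths[name]}\n")
    for res in results:
        seq = (sequences or {}).get(res.read_id, "*")
        if res.ml == 0:
            dest.write(
                f"{res.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\tXO:Z:{res.mode}\n"
            )
            continue
        for i, aln in enumerate(res.alignments):
            flag = 0
            if aln.strand == "-":
                flag |= 16
            if i > 0:
                flag |= 256
            mapq = 255 if res.ml == 1 else 0
            out_seq = seq
            if seq != "*" and aln.strand == "-":
                out_seq = reverse_complement(seq)
            dest.write(
                f"{res.read_id}\t{flag}\t{aln.chrom}\t{aln.start}\t{mapq}\t"
                f"{_cigar(aln.blocks)}\t*\t0\t0\t{out_seq}\t*\t"
                f"NM:i:{aln.mismatches}\tXO:Z:{res.mode}\n"
            )


def _blocks_from_cigar(chrom: str, start: int, strand: str, cigar: str) -> tuple[GenomicInterval, ...]:
    blocks: list[GenomicInterval] = []
    pos = start
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "M":
            blocks.append(GenomicInterval(chrom, pos, pos + n - 1, strand))
            pos += n
        elif ch == "N":
            pos += n
        else:
            raise ValueError(f"unsupported CIGAR op {ch!r} (dialect is M/N only)")
    return tuple(blocks)


def read_sam(source: IO[str] | str) -> list[MappingResult]:
    """Read the SAM dialect written by `write_sam` back into MappingResults."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_sam(fh)
    order: list[str] = []
    seen: set[str] = set()
    grouped: dict[str, dict] = {}
    for line in source:
        if line.startswith("@"):
            continue
        fields = line.rstrip("\n").split("\t")
        qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
        flag = int(flag_s)
        tags = dict(
            (t.split(":", 2)[0], t.split(":", 2)[2]) for t in fields[11:] if ":" in t
        )
        mode = tags.get("XO", MODE_NONE)
        entry = grouped.setdefault(qname, {"mode": mode, "alignments": []})
        if qname not in seen:
            seen.add(qname)
            order.append(qname)
        if flag & 4:
            continue
        strand = "-" if flag & 16 else "+"
        blocks = _blocks_from_cigar(rname, int(pos_s), strand, cigar)
        entry["alignments"].append(
            Alignment(qname, rname, strand, blocks, int(tags.get("NM", 0)))
        )
    out = []
    for qname in order:
        entry = grouped[qname]
        alns = sorted(
            entry["alignments"], key=lambda a: (a.chrom, a.start, a.strand, a.end)
        )
        out.append(MappingResult(qname, entry["mode"], tuple(alns)))
    return out
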