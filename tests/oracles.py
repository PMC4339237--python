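"""Independent brute-force oracles used to validate the mapper and the
coordinate projection.  These deliberately re-derive everything from first
principles (full scans over every position, orientation and split point;
per-base coordinate maps) and share no search code with the package."""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from annoquant.annotation import GenomicInterval, Transcript, reverse_complement


def _enc(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def transcript_base_coords(transcript: Transcript) -> list[int]:
    """Genomic coordinate of every transcript base, in transcription order."""
    coords: list[int] = []
    if transcript.strand == "+":
        for e in transcript.exons:
            coords.extend(range(e.start, e.end + 1))
    else:
        for e in reversed(transcript.exons):
            coords.extend(range(e.end, e.start - 1, -1))
    return coords


def blocks_from_positions(chrom: str, strand: str, positions) -> tuple:
    """Group genomic positions into maximal runs of consecutive coordinates."""
    pts = sorted(positions)
    blocks = []
    run_start = prev = pts[0]
    for p in pts[1:]:
        if p == prev + 1:
            prev = p
            continue
        blocks.append(GenomicInterval(chrom, run_start, prev, strand))
        run_start = prev = p
    blocks.append(GenomicInterval(chrom, run_start, prev, strand))
    return tuple(blocks)


def project_oracle(transcript: Transcript, offset: int, length: int) -> tuple:
    """Per-base coordinate-map projection of a transcript window."""
    coords = transcript_base_coords(transcript)
    window = coords[offset : offset + length]
    return blocks_from_positions(transcript.chrom, transcript.strand, window)


def contiguous_placements(genome_seq: str, read: str, max_mm: int):
    """All (start0, mismatches) contiguous placements, full scan."""
    g, r = _enc(genome_seq), _enc(read)
    L, n = len(r), len(g)
    if n < L:
        return []
    mm = (sliding_window_view(g, L) != r).sum(axis=1)
    return [(int(i), int(m)) for i in np.flatnonzero(mm <= max_mm) for m in [mm[i]]]


def spliced_placements(
    genome_seq: str, read: str, max_mm: int, min_anchor: int, min_intron: int, max_intron: int
):
    """All (left0, split, right0, mismatches) two-segment placements, by
    enumerating every split point and every left/right position."""
    g, r = _enc(genome_seq), _enc(read)
    L, n = len(r), len(g)
    out = []
    if L < 2 * min_anchor or n < L:
        return out
    mis = sliding_window_view(g, L) != r  # [pos, read_offset]
    cum = np.cumsum(mis, axis=1)
    for s in range(min_anchor, L - min_anchor + 1):
        left_mm = cum[:, s - 1]
        rlen = L - s
        right_mm = (sliding_window_view(g, rlen) != r[s:]).sum(axis=1)
        lefts = np.flatnonzero(left_mm <= max_mm)
        rights = np.flatnonzero(right_mm <= max_mm)
        if len(lefts) == 0 or len(rights) == 0:
            continue
        for l in lefts:
            lo = l + s + min_intron
            hi = l + s + max_intron
            for r0 in rights[(rights >= lo) & (rights <= hi)]:
                total = int(left_mm[l]) + int(right_mm[r0])
                if total <= max_mm:
                    out.append((int(l), s, int(r0), total))
    return out


def genome_map_oracle(genome, read, max_mm, min_anchor, min_intron, max_intron):
    """Reference result of genome-mode mapping: the set of placement keys of
    the minimal-mismatch stratum, with the contiguous-beats-spliced rule."""
    candidates = {}  # placement_key -> mm
    contig_best = max_mm + 1
    per_strand = []
    for strand, seq in (("+", read), ("-", reverse_complement(read))):
        for chrom in sorted(genome.keys()):
            for start0, mm in contiguous_placements(genome[chrom], seq, max_mm):
                key = (chrom, strand, ((start0 + 1, start0 + len(read)),))
                if mm < candidates.get(key, max_mm + 1):
                    candidates[key] = mm
                contig_best = min(contig_best, mm)
        per_strand.append((strand, seq))
    spliced_budget = min(max_mm, contig_best - 1)
    if spliced_budget >= 0:
        for strand, seq in per_strand:
            for chrom in sorted(genome.keys()):
                for l, s, r0, mm in spliced_placements(
                    genome[chrom], seq, spliced_budget, min_anchor, min_intron, max_intron
                ):
                    key = (
                        chrom,
                        strand,
                        ((l + 1, l + s), (r0 + 1, r0 + len(read) - s)),
                    )
                    if mm < candidates.get(key, max_mm + 1):
                        candidates[key] = mm
    if not candidates:
        return frozenset()
    best = min(candidates.values())
    return frozenset(k for k, v in candidates.items() if v == best)


def transcriptome_map_oracle(genome, model, read, max_mm):
    """Reference transcriptome-mode result: scan every transcript sequence
    by full sliding-window comparison, project hits per-base, collapse."""
    from annoquant.annotation import spliced_sequence

    candidates = {}
    for tx in model.transcripts():
        if tx.chrom not in genome:
            continue
        tseq = spliced_sequence(genome, tx)
        for flipped, seq in ((False, read), (True, reverse_complement(read))):
            for off0, mm in contiguous_placements(tseq, seq, max_mm):
                blocks = project_oracle(tx, off0, len(read))
                strand = tx.strand
                if flipped:
                    strand = "-" if strand == "+" else "+"
                key = (tx.chrom, strand, tuple((b.start, b.end) for b in blocks))
                if mm < candidates.get(key, max_mm + 1):
                    candidates[key] = mm
    if not candidates:
        return frozenset()
    best = min(candidates.values())
    return frozenset(k for k, v in candidates.items() if v == best)
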