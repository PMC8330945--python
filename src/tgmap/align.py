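"""Minimal deterministic read aligner and coverage computation.

Designed for synthetic toy genomes: an exact k-mer anchor index drives
ungapped end-to-end verification and exact-match local extension.  Instead
of a probabilistic mapping quality, each alignment carries a boolean
``unique`` flag (True when the placement is supported by a k-mer occurring
exactly once in the reference), which downstream filters use the way a
MAPQ > 30 cut-off is used on real data.

Determinism: ties between equally good placements are broken by the
lexicographically smallest (chrom, position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .regions import Genome, revcomp

END_TO_END = "end_to_end"
LOCAL = "local"


@dataclass
class AnchorIndex:
    """Exact k-mer index of a reference genome."""

    name: str
    k: int
    genome: Genome
    kmers: Dict[str, List[Tuple[str, int]]]

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        return self.kmers.get(kmer, [])

    def is_unique(self, kmer: str) -> bool:
        return len(self.kmers.get(kmer, ())) == 1


def index_reference(genome: Genome, k: int, name: str = "ref") -> AnchorIndex:
    """Index every k-mer of the reference with all positions.

    ``k`` must be at least 11 and no longer than the shortest chromosome.
    """
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    shortest = min(len(s) for s in genome.chroms.values())
    if k > shortest:
        raise ValueError(f"k={k} longer than shortest chromosome ({shortest} bp)")
    kmers: Dict[str, List[Tuple[str, int]]] = {}
    for chrom, seq in genome.chroms.items():
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            kmers.setdefault(kmer, []).append((chrom, pos))
    return AnchorIndex(name=name, k=k, genome=genome, kmers=kmers)


@dataclass
class Alignment:
    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    read_length: int
    strand: str
    mode: str
    unique: bool
    mismatches: int = 0
    clipped: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def aligned_length(self) -> int:
        return self.read_end - self.read_start


def _candidate_diagonals(
    index: AnchorIndex, read: str, stride: int
) -> Dict[Tuple[str, int], List[Tuple[int, bool]]]:
    """Anchor hits grouped by (chrom, diagonal = ref_pos - read_pos).

    Values are lists of (read_pos, unique_flag).
    """
    k = index.k
    diags: Dict[Tuple[str, int], List[Tuple[int, bool]]] = {}
    offsets = list(range(0, len(read) - k + 1, stride))
    last = len(read) - k
    if offsets and offsets[-1] != last:
        offsets.append(last)  # always test the terminal k-mer
    for off in offsets:
        hits = index.lookup(read[off : off + k])
        if not hits or len(hits) > 8:  # highly repetitive anchors are skipped
            continue
        uniq = len(hits) == 1
        for chrom, pos in hits:
            diags.setdefault((chrom, pos - off), []).append((off, uniq))
    return diags


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _end_to_end_candidates(index, read, stride):
    """Verified full-length ungapped placements of the read (one strand)."""
    out = []
    n = len(read)
    limit = int(0.02 * n)
    for (chrom, diag), anchors in _candidate_diagonals(index, read, stride).items():
        if diag < 0 or diag + n > index.genome.length(chrom):
            continue
        ref = index.genome[chrom][diag : diag + n]
        mm = _count_mismatches(read, ref, limit)
        if mm <= limit:
            uniq = any(u for _, u in anchors)
            out.append((chrom, diag, mm, uniq))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _extend_exact(read: str, ref: str, read_pos: int, ref_pos: int) -> Tuple[int, int]:
    """Maximal exact match around a seed; returns (read_start, read_end)."""
    s = 0
    while read_pos - s - 1 >= 0 and ref_pos - s - 1 >= 0 and read[read_pos - s - 1] == ref[ref_pos - s - 1]:
        s += 1
    e = 0
    while (
        read_pos + e < len(read)
        and ref_pos + e < len(ref)
        and read[read_pos + e] == ref[ref_pos + e]
    ):
        e += 1
    return read_pos - s, read_pos + e


def map_read(
    index: AnchorIndex,
    read: str,
    mode: str = END_TO_END,
    read_id: str = "read",
    stride: int = 1,
) -> List[Alignment]:
    """Map one read against the index.

    ``end_to_end`` returns at most one full-length ungapped alignment
    (<= 2% mismatches); ``local`` returns the longest exactly matching
    contiguous segment with the remainder reported as clipped intervals.
    Both strands are searched; '-' strand alignments report read coordinates
    on the original read.
    """
    read = read.upper()
    if len(read) < index.k:
        raise ValueError(f"read shorter than k={index.k}")
    if mode not in (END_TO_END, LOCAL):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == END_TO_END:
        best: Optional[Alignment] = None
        n_placements = 0
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            cands = _end_to_end_candidates(index, oriented, stride)
            n_placements += len(cands)
            for chrom, pos, mm, uniq in cands:
                aln = Alignment(
                    read_id=read_id,
                    chrom=chrom,
                    ref_start=pos,
                    ref_end=pos + len(read),
                    read_start=0,
                    read_end=len(read),
                    read_length=len(read),
                    strand=strand,
                    mode=END_TO_END,
                    unique=uniq,
                    mismatches=mm,
                )
                if best is None or (aln.mismatches, aln.chrom, aln.ref_start) < (
                    best.mismatches,
                    best.chrom,
                    best.ref_start,
                ):
                    best = aln
        if best is None:
            return []
        if n_placements > 1:
            best.unique = False
        return [best]

    # local mode: longest exact segment wins, ties by leftmost reference pos
    best_seg: Optional[Alignment] = None
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        for (chrom, diag), anchors in _candidate_diagonals(index, oriented, stride).items():
            ref = index.genome[chrom]
            seen_spans = set()
            for read_pos, _ in anchors:
                ref_pos = diag + read_pos
                rs, re_ = _extend_exact(oriented, ref, read_pos, ref_pos)
                if (rs, re_) in seen_spans:
                    continue
                seen_spans.add((rs, re_))
                uniq = any(
                    u for rp, u in anchors if rs <= rp and rp + index.k <= re_
                )
                if strand == "+":
                    o_rs, o_re = rs, re_
                else:  # map back to original read coordinates
                    o_rs, o_re = len(read) - re_, len(read) - rs
                clipped = []
                if o_rs > 0:
                    clipped.append((0, o_rs))
                if o_re < len(read):
                    clipped.append((o_re, len(read)))
                aln = Alignment(
                    read_id=read_id,
                    chrom=chrom,
                    ref_start=diag + rs,
                    ref_end=diag + re_,
                    read_start=o_rs,
                    read_end=o_re,
                    read_length=len(read),
                    strand=strand,
                    mode=LOCAL,
                    unique=uniq,
                    clipped=clipped,
                )
                key = (-aln.aligned_length, aln.chrom, aln.ref_start)
                best_key = (
                    (-best_seg.aligned_length, best_seg.chrom, best_seg.ref_start)
                    if best_seg is not None
                    else None
                )
                if best_key is None or key < best_key:
                    best_seg = aln
    return [best_seg] if best_seg is not None else []


@dataclass
class CoverageTrack:
    """Per-base coverage arrays keyed by chromosome."""

    counts: Dict[str, np.ndarray]
    provenance: Dict[str, object] = field(default_factory=dict)

    def window_sums(self, window: int) -> Dict[str, np.ndarray]:
        """Sum coverage over non-overlapping windows of ``window`` bp."""
        if window <= 0:
            raise ValueError("window must be positive")
        out = {}
        for chrom, arr in self.counts.items():
            n_win = int(np.ceil(len(arr) / window))
            padded = np.zeros(n_win * window, dtype=np.int64)
            padded[: len(arr)] = arr
            out[chrom] = padded.reshape(n_win, window).sum(axis=1)
        return out

    @property
    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))


def coverage(
    alignments: List[Alignment],
    genome: Genome,
    unique_only: bool = True,
    mode: Optional[str] = None,
) -> CoverageTrack:
    """Per-base coverage of alignments passing the filters."""
    counts = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.chroms.items()}
    for aln in alignments:
        if unique_only and not aln.unique:
            continue
        if mode is not None and aln.mode != mode:
            continue
        counts[aln.chrom][aln.ref_start : aln.ref_end] += 1
    return CoverageTrack(
        counts=counts, provenance={"unique_only": unique_only, "mode": mode}
    )
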