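"""Long-read validation of a candidate reconstruction.

Cas9-targeted nanopore sequencing yields long reads tiling an insertion.
Each read is compared to a candidate reference by exact unique-k-mer
anchoring (default 20-mers sampled every 5 bp of the read, kept only when
they occur exactly once in the reference).  A read supports the
reconstruction when its anchors form a single monotone diagonal chain;
an incorrect reference (e.g. the wild-type genome checked against a read
spanning the insert) produces a broken or offset diagonal.  On-target
enrichment is summarised as the ratio of the observed on-target base
fraction to the target's share of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .regions import GenomicInterval, revcomp
from .synth import SimRead


@dataclass
class DotplotConfig:
    k: int = 20
    stride: int = 5
    #: 'best' keeps the orientation with more anchors; '+' / '-' force one
    strand_policy: str = "best"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.strand_policy not in ("best", "+", "-"):
            raise ValueError("strand_policy must be 'best', '+' or '-'")


@dataclass
class AnchorSet:
    """Unique-k-mer anchors of one read against a reference."""

    read_id: str
    strand: str  # orientation of the read that produced the anchors
    anchors: List[Tuple[int, int]]  # (read position on oriented read, ref position)
    read_length: int
    k: int

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def diagonals(self) -> np.ndarray:
        return np.array([r - q for q, r in self.anchors], dtype=float)


def unique_kmer_positions(reference: str, k: int) -> Dict[str, int]:
    """Map of each k-mer occurring exactly once in the reference to its
    position; repeated k-mers are excluded."""
    seen: Dict[str, int] = {}
    dup: set = set()
    for pos in range(len(reference) - k + 1):
        kmer = reference[pos : pos + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = pos
    return seen


def _scan(read: str, table: Dict[str, int], k: int, stride: int) -> List[Tuple[int, int]]:
    out = []
    for off in range(0, len(read) - k + 1, stride):
        pos = table.get(read[off : off + k])
        if pos is not None:
            out.append((off, pos))
    return out


def dotplot_anchors(
    read: Union[SimRead, str],
    reference: str,
    config: Optional[DotplotConfig] = None,
    unique_table: Optional[Dict[str, int]] = None,
) -> AnchorSet:
    """Exact unique-k-mer anchors of a read against one reference sequence.

    Every ``stride``-th k-mer of the read is kept iff it occurs exactly once
    in the reference.  Under the default strand policy both orientations are
    scanned and the one yielding more anchors is reported (nanopore reads
    are unoriented); read positions refer to the winning orientation.
    """
    config = config or DotplotConfig()
    read_id, seq = (read.id, read.sequence) if isinstance(read, SimRead) else ("read", read)
    seq = seq.upper()
    if len(seq) < config.k:
        raise ValueError(f"read shorter than k={config.k}")
    table = (
        unique_table
        if unique_table is not None
        else unique_kmer_positions(reference.upper(), config.k)
    )
    candidates = {}
    if config.strand_policy in ("best", "+"):
        candidates["+"] = _scan(seq, table, config.k, config.stride)
    if config.strand_policy in ("best", "-"):
        candidates["-"] = _scan(revcomp(seq), table, config.k, config.stride)
    strand = max(candidates, key=lambda s: (len(candidates[s]), s))
    return AnchorSet(
        read_id=read_id,
        strand=strand,
        anchors=candidates[strand],
        read_length=len(seq),
        k=config.k,
    )


def _longest_increasing_chain(anchors: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Longest chain with strictly increasing reference position (anchors
    are already sorted by read position).  O(n log n) patience sorting."""
    import bisect

    if not anchors:
        return []
    tails: List[int] = []  # ref positions of chain tails
    tail_idx: List[int] = []
    prev = [-1] * len(anchors)
    for i, (_, ref) in enumerate(anchors):
        j = bisect.bisect_left(tails, ref)
        if j == len(tails):
            tails.append(ref)
            tail_idx.append(i)
        else:
            tails[j] = ref
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = prev[i]
    return chain[::-1]


@dataclass
class ReadSupport:
    """Monotone-diagonal verdict for one read against a candidate genome.

    ``verdict`` is ``supported`` (one monotone diagonal), ``rejected``
    (breaks/offsets or a scattered chain) or ``uninformative`` (too few
    unique anchors — e.g. a read confined to a block that the candidate
    genome itself duplicates, where no k-mer is unique).
    """

    read_id: str
    n_anchors: int
    chain_length: int
    verdict: str
    breaks: List[Tuple[int, int]] = field(default_factory=list)  # (read pos, ref offset jump)
    strand: str = "+"

    @property
    def supported(self) -> bool:
        return self.verdict == "supported"


def validate_reconstruction(
    reads: Sequence[SimRead],
    candidate_reference: str,
    config: Optional[DotplotConfig] = None,
    diagonal_tolerance: int = 50,
    drift_per_gap_bp: float = 0.01,
    min_anchors: int = 5,
    min_chain_fraction: float = 0.9,
) -> List[ReadSupport]:
    """Check whether each read's anchors form one monotone diagonal.

    The longest increasing anchor chain is extracted; offsets between
    consecutive chain anchors larger than ``diagonal_tolerance`` bp are
    reported as breaks.  The tolerance grows by ``drift_per_gap_bp`` per
    base of anchor gap, because indel errors drift the diagonal in
    proportion to the anchor-free stretch crossed (long gaps arise
    legitimately over blocks the reconstruction itself duplicates, where no
    k-mer is unique).  A read supports the reconstruction when it has no
    breaks and the chain retains at least ``min_chain_fraction`` of the
    anchors.
    """
    config = config or DotplotConfig()
    table = unique_kmer_positions(candidate_reference.upper(), config.k)
    reports = []
    for read in reads:
        aset = dotplot_anchors(read, candidate_reference, config, unique_table=table)
        chain = _longest_increasing_chain(aset.anchors)
        breaks: List[Tuple[int, int]] = []
        for (q0, r0), (q1, r1) in zip(chain, chain[1:]):
            jump = (r1 - q1) - (r0 - q0)
            if abs(jump) > diagonal_tolerance + drift_per_gap_bp * (q1 - q0):
                breaks.append((q1, jump))
        if aset.n_anchors < min_anchors:
            verdict = "uninformative"
        elif breaks or len(chain) < min_chain_fraction * aset.n_anchors:
            verdict = "rejected"
        else:
            verdict = "supported"
        reports.append(
            ReadSupport(
                read_id=aset.read_id,
                n_anchors=aset.n_anchors,
                chain_length=len(chain),
                verdict=verdict,
                breaks=breaks,
                strand=aset.strand,
            )
        )
    return reports


def enrichment_ratio(
    reads: Sequence[SimRead],
    target_intervals: Sequence[GenomicInterval],
    genome_length: int,
) -> float:
    """On-target enrichment: (fraction of read bases on target) divided by
    (target length / genome length).

    Read origins are taken from the generator truth tags
    (``origin = (chrom, start, end)``).
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    target_len = sum(iv.length for iv in target_intervals)
    if target_len <= 0:
        raise ValueError("target fraction must be > 0")
    total = 0
    on_target = 0
    for read in reads:
        origin = read.tags.get("origin")
        if origin is None:
            raise ValueError(f"read {read.id} lacks an origin truth tag")
        chrom, start, end = origin
        total += end - start
        for iv in target_intervals:
            if iv.chrom == chrom:
                on_target += max(0, min(end, iv.end) - max(start, iv.start))
    if total == 0:
        raise ValueError("no read bases")
    return (on_target / total) / (target_len / genome_length)
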