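"""Targeted-locus-amplification (TLA) integration mapping.

TLA produces chimeric proximity-ligation reads enriched around a viewpoint.
The analysis locates a transgene integration in four steps:

1. window scan — unique end-to-end host coverage summed over large
   non-overlapping windows picks the candidate integration window;
2. motif filtering/splitting — reads that fail end-to-end mapping are split
   at the restriction motif (the motif stays with the upstream piece, since
   religation leaves a single motif copy per ligation junction); pieces that
   map end-to-end to either reference are digestion/religation products and
   are discarded, leaving candidate hybrid-junction pieces;
3. breakpoint detection — local (clipped) mapping of the surviving pieces
   yields coverage whose sharp steps mark candidate breakpoints;
4. junction consensus — clipped overhangs sharing an anchored locus are
   collapsed into a majority consensus whose local mapping identifies the
   partner side, giving base-pair-resolved junction calls.

A separate multi-orientation concatemer test counts reads supporting each
tandem configuration (tail-to-head / tail-to-tail / head-to-head).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .align import (
    END_TO_END,
    LOCAL,
    Alignment,
    AnchorIndex,
    CoverageTrack,
    coverage,
    index_reference,
    map_read,
)
from .regions import Genome, GenomicInterval, revcomp
from .synth import SimRead


@dataclass
class TlaConfig:
    scan_window: int = 1_000_000
    restriction_motif: str = "CATG"
    min_split_length: int = 26  # "more than 25 bp"
    exclusion_intervals: List[GenomicInterval] = field(default_factory=list)
    drop_fraction: float = 0.8
    min_support: int = 2
    anchor_k: int = 21

    def __post_init__(self) -> None:
        if self.scan_window <= 0:
            raise ValueError("scan_window must be positive")
        if len(self.restriction_motif) < 4:
            raise ValueError("restriction motif must be at least 4 bp")


@dataclass
class JunctionCall:
    """A base-pair-resolved hybrid junction.

    ``side_a`` is the upstream side (its position is the last base before
    the junction), ``side_b`` the downstream side (first base after it).
    """

    side_a: Tuple[str, int, str]  # (chrom/reference, position, orientation)
    side_b: Tuple[str, int, str]
    support: int
    consensus: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("junction support must be >= 1")


@dataclass
class IntegrationReport:
    candidate_window: GenomicInterval
    breakpoints: List[int]
    junctions: List[JunctionCall]
    tandem_counts: Dict[str, int]
    copy_structure: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "candidate_window": str(self.candidate_window),
                "breakpoints": self.breakpoints,
                "junctions": [
                    {
                        "side_a": list(j.side_a),
                        "side_b": list(j.side_b),
                        "support": j.support,
                        "consensus": j.consensus,
                        "label": j.label,
                    }
                    for j in self.junctions
                ],
                "tandem_counts": self.tandem_counts,
                "copy_structure": self.copy_structure,
            },
            indent=2,
        )


def scan_integration_site(track: CoverageTrack, config: TlaConfig) -> GenomicInterval:
    """Window with maximal summed end-to-end coverage, excluding windows
    overlapping the configured exclusion intervals (e.g. the transgene's
    source locus).  Ties break to the lowest coordinate."""
    sums = track.window_sums(config.scan_window)
    best: Optional[Tuple[int, str, int]] = None
    any_signal = False
    for chrom in sorted(sums):
        arr = sums[chrom]
        for widx, val in enumerate(arr):
            win = GenomicInterval(
                chrom,
                widx * config.scan_window,
                min((widx + 1) * config.scan_window, len(track.counts[chrom])),
            )
            if any(win.overlaps(iv) for iv in config.exclusion_intervals):
                continue
            if val > 0:
                any_signal = True
            key = (-int(val), chrom, win.start)
            if best is None or key < best[:3]:
                best = (key[0], chrom, win.start)
    if best is None or not any_signal:
        raise ValueError("coverage track has no signal outside exclusions")
    chrom, start = best[1], best[2]
    return GenomicInterval(
        chrom, start, min(start + config.scan_window, len(track.counts[chrom]))
    )


def catg_filter_unmapped(
    reads: Iterable[SimRead],
    end_to_end_mapped_ids: Set[str],
    config: TlaConfig,
) -> List[SimRead]:
    """Reads that failed end-to-end mapping AND contain no restriction
    motif: religation events are excluded, candidate hybrids kept."""
    motif = config.restriction_motif
    return [
        r
        for r in reads
        if r.id not in end_to_end_mapped_ids and motif not in r.sequence.upper()
    ]


def split_at_motif(seq: str, motif: str) -> List[str]:
    """Cut a sequence at every motif occurrence, the motif staying with the
    upstream piece (religation leaves one motif copy per junction)."""
    pieces = []
    start = 0
    i = seq.find(motif)
    while i != -1:
        pieces.append(seq[start : i + len(motif)])
        start = i + len(motif)
        i = seq.find(motif, start)
    if start < len(seq):
        pieces.append(seq[start:])
    return pieces


def catg_split_unmapped(
    reads: Iterable[SimRead],
    config: TlaConfig,
    host_index: AnchorIndex,
    transgene_index: AnchorIndex,
) -> List[SimRead]:
    """Split unmapped reads at the restriction motif and keep the pieces
    that are long enough (> 25 bp) and do not map end-to-end to either the
    host or the transgene reference — the candidate hybrid-junction pieces."""
    out: List[SimRead] = []
    for read in reads:
        for pidx, piece in enumerate(split_at_motif(read.sequence.upper(), config.restriction_motif)):
            if len(piece) < config.min_split_length:
                continue
            mapped = False
            for index in (host_index, transgene_index):
                if len(piece) >= index.k and map_read(
                    index, piece, END_TO_END, stride=max(1, index.k // 2)
                ):
                    mapped = True
                    break
            if mapped:
                continue
            out.append(
                SimRead(
                    id=f"{read.id}/{pidx}",
                    sequence=piece,
                    tags={"parent": read.id},
                )
            )
    return out


def detect_breakpoints(
    local_coverage: CoverageTrack,
    candidate: GenomicInterval,
    drop_fraction: float = 0.8,
    local_window: int = 250,
) -> List[int]:
    """Positions where clipped-read coverage steps by more than
    ``drop_fraction`` of the local maximum between adjacent bases.

    ``local_window`` sets how far the local maximum is searched; it must be
    narrower than the spacing of nearby junctions (a target-site duplication
    puts the two integration breakpoints only a few hundred bp apart), or a
    strong junction masks a weaker neighbour.
    """
    arr = local_coverage.counts[candidate.chrom][candidate.start : candidate.end]
    if arr.size == 0:
        raise ValueError("empty candidate window")
    diffs = np.diff(arr.astype(float))
    hits = []
    for i in np.nonzero(diffs)[0]:
        lo = max(0, i - local_window)
        hi = min(arr.size, i + local_window + 1)
        local_max = arr[lo:hi].max()
        if local_max > 0 and abs(diffs[i]) > drop_fraction * local_max:
            hits.append(candidate.start + i + 1)
    return hits


def _canonical_local(aln: Alignment, seq: str) -> Tuple[Alignment, str]:
    """Flip '-' strand local alignments so the anchored segment reads
    forward; coordinates are adjusted to the flipped sequence."""
    if aln.strand == "+":
        return aln, seq
    n = len(seq)
    flipped = revcomp(seq)
    rs, re_ = n - aln.read_end, n - aln.read_start
    clipped = []
    if rs > 0:
        clipped.append((0, rs))
    if re_ < n:
        clipped.append((re_, n))
    new = Alignment(
        read_id=aln.read_id,
        chrom=aln.chrom,
        ref_start=aln.ref_start,
        ref_end=aln.ref_end,
        read_start=rs,
        read_end=re_,
        read_length=n,
        strand="+",
        mode=aln.mode,
        unique=aln.unique,
        clipped=clipped,
    )
    return new, flipped


def _majority_consensus(seqs: List[str], right_justified: bool = False) -> str:
    """Per-position majority base; ties resolved alphabetically."""
    if right_justified:
        seqs = [s[::-1] for s in seqs]
    length = max(len(s) for s in seqs)
    out = []
    for i in range(length):
        counts: Dict[str, int] = defaultdict(int)
        for s in seqs:
            if i < len(s):
                counts[s[i]] += 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    cons = "".join(out)
    return cons[::-1] if right_justified else cons


def junction_consensus(
    pieces: Iterable[SimRead],
    indexes: Dict[str, AnchorIndex],
    min_support: int = 2,
    flank: int = 30,
) -> List[JunctionCall]:
    """Group clipped local alignments by anchored locus and clip side,
    build a majority consensus of the overhangs, and map the consensus to
    identify the partner side of each hybrid junction."""
    index_order = sorted(indexes)
    groups: Dict[Tuple[str, str, int, str], List[Tuple[str, str]]] = defaultdict(list)
    # key -> list of (overhang, anchored flank sequence from the read)
    for piece in pieces:
        best: Optional[Tuple[int, str, Alignment]] = None
        for name in index_order:
            alns = map_read(indexes[name], piece.sequence, LOCAL, read_id=piece.id)
            if not alns:
                continue
            aln = alns[0]
            key = (-aln.aligned_length, name)
            if best is None or key < (-best[2].aligned_length, best[1]):
                best = (0, name, aln)
        if best is None:
            continue
        name, aln = best[1], best[2]
        aln, seq = _canonical_local(aln, piece.sequence)
        if not aln.clipped or not aln.unique:
            continue
        for clip_start, clip_end in aln.clipped:
            overhang = seq[clip_start:clip_end]
            if len(overhang) < 5:
                continue
            if clip_start == aln.read_end:  # clip on the right of the anchor
                jpos = aln.ref_end  # first unmatched reference position
                side = "right"
                anchored = seq[max(0, aln.read_end - flank) : aln.read_end]
            else:  # clip on the left
                jpos = aln.ref_start
                side = "left"
                anchored = seq[aln.read_start : aln.read_start + flank]
            groups[(name, aln.chrom, jpos, side)].append((overhang, anchored))

    calls: List[JunctionCall] = []
    for (name, chrom, jpos, side), members in groups.items():
        if len(members) < min_support:
            continue
        overhangs = [m[0] for m in members]
        cons = _majority_consensus(overhangs, right_justified=(side == "left"))
        # locate the partner side by local-mapping the consensus overhang
        partner: Optional[Tuple[str, str, Alignment]] = None
        for other in index_order:
            if len(cons) < indexes[other].k:
                continue
            alns = map_read(indexes[other], cons, LOCAL, read_id="consensus")
            if not alns:
                continue
            aln = alns[0]
            if partner is None or aln.aligned_length > partner[2].aligned_length:
                partner = (other, aln.chrom, aln)
        if partner is None:
            continue
        pname, pchrom, paln = partner
        paln, cons_oriented = _canonical_local(paln, cons)
        anchored_flank = members[0][1]
        if side == "right":
            # anchored side is upstream: last matching base, partner's first
            side_a = (chrom, jpos - 1, "+")
            pfirst = paln.ref_start - paln.read_start
            side_b = (pchrom, pfirst, "+")
            consensus = anchored_flank + cons
        else:
            # anchored side is downstream; partner (overhang) is upstream
            plast = paln.ref_end - 1 + (len(cons_oriented) - paln.read_end)
            side_a = (pchrom, plast, "+")
            side_b = (chrom, jpos, "+")
            consensus = cons + anchored_flank
        calls.append(
            JunctionCall(
                side_a=side_a,
                side_b=side_b,
                support=len(members),
                consensus=consensus,
                label=side,
            )
        )
    return _merge_reciprocal(calls)


def _merge_reciprocal(calls: List[JunctionCall], tol: int = 1) -> List[JunctionCall]:
    """Merge junction calls discovered from both anchored sides."""
    merged: List[JunctionCall] = []
    for call in sorted(calls, key=lambda c: -c.support):
        hit = None
        for m in merged:
            if (
                m.side_a[0] == call.side_a[0]
                and m.side_b[0] == call.side_b[0]
                and abs(m.side_a[1] - call.side_a[1]) <= tol
                and abs(m.side_b[1] - call.side_b[1]) <= tol
            ):
                hit = m
                break
        if hit is None:
            merged.append(call)
        else:
            hit.support += call.support
    return sorted(merged, key=lambda c: (c.side_a[0], c.side_a[1]))


TANDEM_ORIENTATIONS = ("+", "+", "-", "+")  # -> -> <- ->


def tandem_configuration(
    reads: Iterable[SimRead],
    fosmid_sequence: str,
    k: int = 21,
    min_flank: int = 21,
    motif: Optional[str] = "CATG",
) -> Dict[str, int]:
    """Count unique end-to-end reads spanning each tandem junction type on a
    multi-orientation concatemer reference (-> -> <- ->).

    Ligation products chain several restriction fragments, so whole products
    rarely map end-to-end anywhere; when ``motif`` is given, reads are first
    cut at the religation motif and the resulting single-fragment pieces are
    mapped.  Junction support requires the piece to cover the junction by at
    least ``min_flank`` bases on both sides.

    No uniqueness filter is applied to the placement: head-to-head and
    tail-to-tail junction sequences are their own reverse complements, so a
    spanning read always has two mirror-image placements around the same
    junction.  Specificity comes from the junction-span requirement itself —
    within-unit reads map inside the copies and never span a junction.
    """
    fosmid_sequence = fosmid_sequence.upper()
    L = len(fosmid_sequence)
    parts = [
        fosmid_sequence if o == "+" else revcomp(fosmid_sequence)
        for o in TANDEM_ORIENTATIONS
    ]
    ref = Genome({"concatemer": "".join(parts)})
    index = index_reference(ref, k, name="concatemer")
    junctions = {
        "tail_to_head": L,  # + | +
        "tail_to_tail": 2 * L,  # + | -
        "head_to_head": 3 * L,  # - | +
    }
    counts = {name: 0 for name in junctions}
    queries: List[str] = []
    for read in reads:
        if motif:
            queries.extend(split_at_motif(read.sequence.upper(), motif))
        else:
            queries.append(read.sequence.upper())
    for qidx, query in enumerate(queries):
        if len(query) < k:
            continue
        alns = map_read(index, query, END_TO_END, read_id=f"q{qidx}", stride=max(1, k // 2))
        if not alns:
            continue
        aln = alns[0]
        for name, jpos in junctions.items():
            if aln.ref_start + min_flank <= jpos <= aln.ref_end - min_flank:
                counts[name] += 1
    return counts


@dataclass
class TlaResult:
    report: IntegrationReport
    end_to_end_coverage: CoverageTrack
    split_local_coverage: CoverageTrack
    n_reads: int
    n_unmapped: int
    n_split_pieces: int


def run_tla(
    reads: Sequence[SimRead],
    host: Genome,
    transgene: Genome,
    fosmid_sequence: Optional[str] = None,
    config: Optional[TlaConfig] = None,
) -> TlaResult:
    """End-to-end TLA analysis: window scan, motif splitting, breakpoint
    detection, junction consensus and tandem-configuration testing."""
    config = config or TlaConfig()
    host_index = index_reference(host, config.anchor_k, name="host")
    tg_index = index_reference(transgene, config.anchor_k, name="transgene")

    e2e_alns: List[Alignment] = []
    mapped_ids: Set[str] = set()
    stride = max(1, config.anchor_k // 2)
    for read in reads:
        if len(read.sequence) < config.anchor_k:
            continue
        alns = map_read(host_index, read.sequence, END_TO_END, read_id=read.id, stride=stride)
        if alns:
            e2e_alns.extend(alns)
            mapped_ids.add(read.id)
    e2e_cov = coverage(e2e_alns, host, unique_only=True, mode=END_TO_END)
    candidate = scan_integration_site(e2e_cov, config)

    unmapped = [r for r in reads if r.id not in mapped_ids]
    pieces = catg_split_unmapped(unmapped, config, host_index, tg_index)

    local_alns: List[Alignment] = []
    for piece in pieces:
        for index in (host_index, tg_index):
            if len(piece.sequence) >= index.k:
                local_alns.extend(
                    map_read(index, piece.sequence, LOCAL, read_id=piece.id)
                )
    host_chrom_names = set(host.chroms)
    host_local = [a for a in local_alns if a.chrom in host_chrom_names]
    local_cov = coverage(host_local, host, unique_only=True, mode=LOCAL)
    breakpoints = detect_breakpoints(local_cov, candidate, config.drop_fraction)

    indexes = {"host": host_index, "transgene": tg_index}
    junctions = junction_consensus(pieces, indexes, min_support=config.min_support)

    tandem = (
        tandem_configuration(reads, fosmid_sequence, k=config.anchor_k)
        if fosmid_sequence
        else {}
    )
    n_copies = tandem.get("tail_to_head", 0)
    host_tg = [
        j
        for j in junctions
        if {j.side_a[0], j.side_b[0]} & host_chrom_names
        and not {j.side_a[0], j.side_b[0]} <= host_chrom_names
    ]
    if n_copies > 0 and len(host_tg) >= 2:
        structure = "tandem tail-to-head: at least one full copy plus a partial copy"
    elif len(host_tg) >= 2:
        structure = "single-copy insertion with both breakpoints resolved"
    else:
        structure = "unresolved"
    report = IntegrationReport(
        candidate_window=candidate,
        breakpoints=breakpoints,
        junctions=junctions,
        tandem_counts=tandem,
        copy_structure=structure,
    )
    return TlaResult(
        report=report,
        end_to_end_coverage=e2e_cov,
        split_local_coverage=local_cov,
        n_reads=len(reads),
        n_unmapped=len(unmapped),
        n_split_pieces=len(pieces),
    )
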