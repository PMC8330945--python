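"""Declarative insertion plans, mutant-genome construction and liftover.

A :class:`RearrangementPlan` describes a single insertion event on a host
chromosome: an ordered list of sequence components (tandem transgene copies,
vector backbone, ...), each in forward or reverse orientation, plus a
target-site duplication (TSD).  Building the mutant genome places, at host
position ``p``::

    host[0:p] + oriented components + host[p-t:p] + host[p:]

so the duplicated host segment ``host[p-t:p]`` ends up flanking the insert
core on both sides, with the left host/insert junction lying between the two
duplicate copies.  The companion :class:`LiftoverMap` converts coordinates
between the wild-type and mutant axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import yaml

from .regions import Genome, GenomicInterval, revcomp


class _InsideInsert:
    """Sentinel returned when a mutant position has no wild-type image."""

    _instance: Optional["_InsideInsert"] = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "INSIDE_INSERT"


INSIDE_INSERT = _InsideInsert()


@dataclass(frozen=True)
class Component:
    """One insert component: a literal sequence or an interval on a named
    source genome, with an orientation ('-' means reverse complement)."""

    sequence: Optional[str] = None
    source: Optional[str] = None
    interval: Optional[GenomicInterval] = None
    orientation: str = "+"

    def __post_init__(self) -> None:
        literal = self.sequence is not None
        ref = self.source is not None and self.interval is not None
        if literal == ref:
            raise ValueError(
                "component must have either a literal sequence or "
                "(source, interval), not both/neither"
            )
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")

    def resolve(self, sources: Dict[str, Genome]) -> str:
        if self.sequence is not None:
            seq = self.sequence.upper()
        else:
            if self.source not in sources:
                raise KeyError(f"unknown source genome {self.source!r}")
            genome = sources[self.source]
            if self.interval.chrom not in genome:
                raise ValueError(
                    f"chromosome {self.interval.chrom!r} absent from source "
                    f"{self.source!r}"
                )
            if self.interval.end > genome.length(self.interval.chrom):
                raise ValueError(f"component interval {self.interval} outside source")
            seq = genome.fetch(
                GenomicInterval(self.interval.chrom, self.interval.start, self.interval.end)
            )
        return revcomp(seq) if self.orientation == "-" else seq

    def to_dict(self) -> dict:
        d: dict = {"orientation": self.orientation}
        if self.sequence is not None:
            d["sequence"] = self.sequence
        else:
            d["source"] = self.source
            d["region"] = str(self.interval)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Component":
        from .regions import parse_region

        if "sequence" in d:
            return cls(sequence=d["sequence"], orientation=d.get("orientation", "+"))
        return cls(
            source=d["source"],
            interval=parse_region(d["region"]),
            orientation=d.get("orientation", "+"),
        )


@dataclass
class RearrangementPlan:
    """Insertion of ordered components at one host position with a TSD."""

    host_chrom: str
    insertion_point: int
    components: List[Component] = field(default_factory=list)
    tsd_length: int = 0

    def __post_init__(self) -> None:
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if self.insertion_point < 0:
            raise ValueError("insertion_point must be >= 0")

    def component_sequences(self, sources: Dict[str, Genome]) -> List[str]:
        return [c.resolve(sources) for c in self.components]

    def added_length(self, sources: Dict[str, Genome]) -> int:
        """Total length added to the host chromosome (components + TSD)."""
        return sum(len(s) for s in self.component_sequences(sources)) + self.tsd_length

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "host_chrom": self.host_chrom,
                "insertion_point": self.insertion_point,
                "tsd_length": self.tsd_length,
                "components": [c.to_dict() for c in self.components],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RearrangementPlan":
        d = yaml.safe_load(text)
        return cls(
            host_chrom=d["host_chrom"],
            insertion_point=int(d["insertion_point"]),
            components=[Component.from_dict(c) for c in d.get("components", [])],
            tsd_length=int(d.get("tsd_length", 0)),
        )


@dataclass
class LiftoverMap:
    """Piecewise monotone coordinate map for one inserted block.

    ``segments`` are ``(wt_start, wt_end, shift)`` triples covering the
    wild-type axis; the mutant image of a wild-type position is ``pos +
    shift``.  ``insert_span`` is the half-open mutant interval occupied by
    the inserted block (components + appended TSD copy), which has no
    wild-type image.
    """

    chrom: str
    wt_length: int
    insertion_point: int
    added_length: int

    @property
    def mut_length(self) -> int:
        return self.wt_length + self.added_length

    @property
    def insert_span(self) -> Tuple[int, int]:
        return (self.insertion_point, self.insertion_point + self.added_length)

    @property
    def segments(self) -> List[Tuple[int, int, int]]:
        p = self.insertion_point
        segs = []
        if p > 0:
            segs.append((0, p, 0))
        if p < self.wt_length:
            segs.append((p, self.wt_length, self.added_length))
        return segs


def lift_position(
    liftover: LiftoverMap, pos: int, direction: str = "wt_to_mut"
) -> Union[int, _InsideInsert]:
    """Map a position across the insertion.

    ``wt_to_mut``: positions left of the insertion point are unchanged,
    positions at/right of it shift by the added length.  ``mut_to_wt``:
    positions inside the inserted block return :data:`INSIDE_INSERT`.
    """
    p, a = liftover.insertion_point, liftover.added_length
    if direction == "wt_to_mut":
        if not 0 <= pos < liftover.wt_length:
            raise ValueError(f"position {pos} outside wild-type chromosome")
        return pos if pos < p else pos + a
    if direction == "mut_to_wt":
        if not 0 <= pos < liftover.mut_length:
            raise ValueError(f"position {pos} outside mutant chromosome")
        if pos < p:
            return pos
        if pos < p + a:
            return INSIDE_INSERT
        return pos - a
    raise ValueError(f"direction must be 'wt_to_mut' or 'mut_to_wt', got {direction!r}")


def build_mutant_genome(
    host: Genome,
    plan: RearrangementPlan,
    sources: Optional[Dict[str, Genome]] = None,
) -> Tuple[Genome, LiftoverMap]:
    """Apply a rearrangement plan to the host genome.

    Returns the mutant genome (all non-target chromosomes untouched) and the
    liftover map for the rearranged chromosome.
    """
    sources = sources or {}
    if plan.host_chrom not in host:
        raise ValueError(f"host chromosome {plan.host_chrom!r} not in genome")
    chrom_seq = host[plan.host_chrom]
    p = plan.insertion_point
    if p > len(chrom_seq):
        raise ValueError(
            f"insertion point {p} beyond chromosome length {len(chrom_seq)}"
        )
    if plan.tsd_length > p:
        raise ValueError(
            f"tsd_length {plan.tsd_length} exceeds upstream host sequence ({p} bp)"
        )
    parts = plan.component_sequences(sources)
    tsd = chrom_seq[p - plan.tsd_length : p] if plan.tsd_length else ""
    insert_block = "".join(parts) + tsd
    mutant_seq = chrom_seq[:p] + insert_block + chrom_seq[p:]

    chroms = dict(host.chroms)
    chroms[plan.host_chrom] = mutant_seq
    liftover = LiftoverMap(
        chrom=plan.host_chrom,
        wt_length=len(chrom_seq),
        insertion_point=p,
        added_length=len(insert_block),
    )
    return Genome(chroms), liftover


def extract_insert(mutant: Genome, liftover: LiftoverMap) -> str:
    """Sequence of the inserted block (components + appended TSD copy)."""
    lo, hi = liftover.insert_span
    return mutant[liftover.chrom][lo:hi]


def count_motif(seq: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``seq`` (non-overlapping, forward strand)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    return seq.upper().count(motif.upper())
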