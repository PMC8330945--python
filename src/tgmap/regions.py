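"""Genomic intervals, genomes and FASTA I/O.

Coordinates are 0-based, half-open throughout the package.  Browser-style
region strings (``chr10:97019222-97019824``) are parsed *as printed*, i.e.
start and end are taken verbatim and the interval length is ``end - start``.
This deliberately skips the usual 1-based-inclusive ``+1`` so that printed
coordinate pairs and printed segment lengths stay mutually consistent (the
602 bp target-site duplication used throughout the worked examples).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)[–-](?P<end>\d+)$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str) -> GenomicInterval:
    """Parse a browser-style ``chrom:start-end`` string.

    Accepts an ASCII hyphen or an en-dash between the coordinates.  The
    returned interval has ``length == end - start``.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    start, end = int(m.group("start")), int(m.group("end"))
    if start > end:
        raise ValueError(f"start > end in region string: {text!r}")
    return GenomicInterval(m.group("chrom"), start, end)


@dataclass
class Genome:
    """Ordered map of chromosome name to nucleotide sequence (A/C/G/T/N).

    Sequences are stored uppercase; lowercase input is normalised on
    construction and on FASTA read.
    """

    chroms: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalised = {}
        for name, seq in self.chroms.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid bases: {sorted(bad)}"
                )
            normalised[name] = seq
        self.chroms = normalised

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __iter__(self) -> Iterator[str]:
        return iter(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.chroms == other.chroms

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; '-' strand returns the reverse complement."""
        seq = self.chroms[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} outside chromosome of length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return revcomp(sub) if interval.strand == "-" else sub


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Raises on an empty file and on duplicate record names.
    """
    chroms: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(chroms)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chroms.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
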