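"""Worked example: reconstruction arithmetic of a characterized fosmid line.

The characterized integration consists of one entire copy of a ~45 kb
fosmid (cloning vector plus the 37,477 bp genomic region
``chr2:75122684-75160161``, carrying three same-orientation CTCF sites),
fused tail-to-head with a partial second copy that extends far enough to
include the first CTCF site, the whole insert flanked by a 602 bp
target-site duplication of the host (``chr10:97019222-97019824``).  The
total inserted block measures 63,812 bp, i.e. an insert span of 63.2 kb of
transgene-derived sequence plus the duplication.

This module rebuilds that configuration on a toy host genome from the
printed parameters alone, so the derived numbers (duplication length,
insert span, CTCF-site count) are recomputed — not stored — and can be
checked against the construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .regions import Genome, GenomicInterval, parse_region
from .rearrange import (
    Component,
    RearrangementPlan,
    build_mutant_genome,
    count_motif,
    extract_insert,
)
from .synth import CTCF_SITE, random_sequence

#: printed coordinates of the target-site duplication on the host
DUPLICATION_REGION = "chr10:97019222-97019824"
#: printed coordinates of the fosmid's genomic cargo on its source chromosome
CARGO_REGION = "chr2:75122684-75160161"
#: printed total length of the inserted block (components + duplication)
TOTAL_INSERT_LENGTH = 63_812
#: nominal fosmid length (vector backbone + cargo), "45 kb-large" clone
FOSMID_LENGTH = 45_000

#: CTCF sites of the cargo, as offsets within the fosmid (vector first);
#: the partial copy extends past the first site only
FOSMID_CTCF_OFFSETS = (12_000, 24_000, 36_000)


@dataclass
class ReconstructionSummary:
    duplication_length_bp: int
    insert_span_bp: int  # transgene-derived sequence, duplication excluded
    total_added_bp: int
    insert_ctcf_sites: int
    partial_copy_length_bp: int

    @property
    def insert_span_kb(self) -> float:
        return round(self.insert_span_bp / 1000.0, 1)


def build_case_study(seed: int = 0) -> Dict[str, object]:
    """Reconstruct the characterized integration on a toy host.

    The host chromosome and fosmid sequences are random (seeded), but every
    size is taken from the printed reconstruction parameters; CTCF-like
    motifs are planted at the fosmid's site offsets.  Returns the genomes,
    plan, liftover and a :class:`ReconstructionSummary` whose fields are
    measured on the built mutant genome.
    """
    rng = np.random.default_rng(seed)
    duplication = parse_region(DUPLICATION_REGION)
    tsd_length = duplication.length
    cargo = parse_region(CARGO_REGION)

    insert_span = TOTAL_INSERT_LENGTH - tsd_length
    partial_length = insert_span - FOSMID_LENGTH
    if partial_length <= 0:
        raise ValueError("printed parameters imply a non-positive partial copy")

    fosmid = list(random_sequence(FOSMID_LENGTH, rng))
    for off in FOSMID_CTCF_OFFSETS:
        fosmid[off : off + len(CTCF_SITE)] = CTCF_SITE
    fosmid_seq = "".join(fosmid)
    if count_motif(fosmid_seq, CTCF_SITE) != len(FOSMID_CTCF_OFFSETS):
        raise RuntimeError("spurious CTCF motif in the random fosmid backbone")

    host_len = 200_000
    insertion_point = 100_000  # toy-host stand-in for the printed breakpoint
    host = Genome({"chr10": random_sequence(host_len, rng)})
    sources = {"fosmid": Genome({"fosmid": fosmid_seq})}

    plan = RearrangementPlan(
        host_chrom="chr10",
        insertion_point=insertion_point,
        components=[
            Component(source="fosmid", interval=GenomicInterval("fosmid", 0, FOSMID_LENGTH)),
            Component(source="fosmid", interval=GenomicInterval("fosmid", 0, partial_length)),
        ],
        tsd_length=tsd_length,
    )
    mutant, liftover = build_mutant_genome(host, plan, sources)
    insert_seq = extract_insert(mutant, liftover)

    summary = ReconstructionSummary(
        duplication_length_bp=tsd_length,
        insert_span_bp=liftover.added_length - tsd_length,
        total_added_bp=liftover.added_length,
        insert_ctcf_sites=count_motif(insert_seq, CTCF_SITE),
        partial_copy_length_bp=partial_length,
    )
    return {
        "host": host,
        "sources": sources,
        "plan": plan,
        "mutant": mutant,
        "liftover": liftover,
        "summary": summary,
        "cargo_length_bp": cargo.length,
    }
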