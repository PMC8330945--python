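"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates a tandem transgene integration: a host chromosome
receives ``n_full_copies`` complete copies of a transgene unit plus one
partial copy (a prefix covering ``partial_fraction`` of the unit), all
tail-to-head, flanked by a target-site duplication of the host.  From the
resulting mutant genome it derives TLA-like proximity-ligation reads,
nanopore-like long reads, windowed depth counts, qPCR Ct tables, Hi-C
contact matrices with power-law decay and tunable boundary insulation, and
4C decay profiles.  Every generator draws from a single explicitly seeded
NumPy random stream and records enough truth to score downstream stages
without re-deriving anything from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .fourc import FourCProfile
from .regions import Genome, GenomicInterval, revcomp
from .rearrange import (
    Component,
    LiftoverMap,
    RearrangementPlan,
    build_mutant_genome,
)

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)

#: a CTCF-like binding-site motif planted in the transgene unit (no CATG)
CTCF_SITE = "CCACCAGGTGGCGCTA"

#: relative offsets of the CTCF sites within the transgene unit; with the
#: default partial_fraction the partial copy carries exactly the first site
CTCF_SITE_OFFSETS = (0.30, 0.60, 0.85)


def random_sequence(n: int, rng: np.random.Generator) -> str:
    return _BASE_LOOKUP[rng.integers(0, 4, size=n)].tobytes().decode()


def digest(seq: str, motif: str) -> List[Tuple[int, int]]:
    """Restriction fragments of ``seq``: cuts fall immediately after each
    motif occurrence, so every fragment except the last ends with the motif
    (NlaIII-style)."""
    cuts = [0]
    i = seq.find(motif)
    while i != -1:
        cuts.append(i + len(motif))
        i = seq.find(motif, i + 1)
    if cuts[-1] != len(seq):
        cuts.append(len(seq))
    return list(zip(cuts[:-1], cuts[1:]))


@dataclass
class HicParams:
    bin_size: int = 10_000
    decay_alpha: float = -1.0
    boundary_insulation_factor: float = 0.5
    domain_insulation_factor: float = 0.3
    mean_count: float = 50.0
    #: host-TAD boundaries (bp).  The insertion splits its host domain into
    #: a larger left and a smaller right sub-domain (about 22 and 10 bins at
    #: the default bin size), mirroring the studied configuration at
    #: bin-count scale.
    domain_breakpoints: Tuple[int, ...] = (980_000, 1_300_000)


@dataclass
class FourCParams:
    mean_fragment_length: int = 2_000
    decay_rate: float = 2e-5  # per bp, exponential decay of expected score
    mean_score: float = 200.0


@dataclass
class ScenarioConfig:
    """Study conditions for the default synthetic integration scenario."""

    seed: int = 42
    host_chrom_length: int = 2_000_000
    transgene_length: int = 40_000
    n_full_copies: int = 1
    partial_fraction: float = 0.55
    tsd_length: int = 600
    insertion_point: int = 1_200_000
    restriction_motif: str = "CATG"
    host_chrom: str = "chrH"
    transgene_name: str = "transgene"
    n_tla_reads: int = 2_000
    tla_neighborhood: int = 50_000
    max_ligation_fragments: int = 4
    hic: HicParams = field(default_factory=HicParams)
    fourc: FourCParams = field(default_factory=FourCParams)
    ct_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.host_chrom_length <= 0 or self.transgene_length <= 0:
            raise ValueError("lengths must be positive")
        if self.transgene_length > self.host_chrom_length:
            raise ValueError("transgene longer than host chromosome")
        if not 0 < self.partial_fraction <= 1:
            raise ValueError("partial_fraction must be in (0, 1]")
        if not 0 <= self.insertion_point <= self.host_chrom_length:
            raise ValueError("insertion point out of range")
        if self.tsd_length > self.insertion_point:
            raise ValueError("tsd_length exceeds sequence upstream of insertion")
        if not 0 < self.hic.boundary_insulation_factor <= 1:
            raise ValueError("insulation factor must be in (0, 1]")


@dataclass
class SimRead:
    id: str
    sequence: str
    tags: Dict[str, object] = field(default_factory=dict)


def write_fastq(reads: Sequence[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path) -> List[SimRead]:
    reads = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - 3, 4):
        reads.append(SimRead(id=lines[i][1:].split()[0], sequence=lines[i + 1]))
    return reads


@dataclass
class ScenarioBundle:
    """A simulated integration scenario plus its ground truth."""

    config: ScenarioConfig
    wildtype: Genome  # host chromosome only
    sources: Dict[str, Genome]  # named source genomes (the transgene unit)
    mutant: Genome
    plan: RearrangementPlan
    liftover: LiftoverMap
    truth: Dict[str, object]

    @property
    def transgene_sequence(self) -> str:
        cfg = self.config
        return self.sources[cfg.transgene_name][cfg.transgene_name]


def _make_transgene(length: int, rng: np.random.Generator) -> str:
    """Random transgene unit with CTCF-like sites planted at fixed relative
    offsets and no spurious CTCF motif elsewhere."""
    seq = random_sequence(length, rng)
    while CTCF_SITE in seq:  # vanishingly unlikely; keep the count exact
        seq = random_sequence(length, rng)
    out = list(seq)
    for off in CTCF_SITE_OFFSETS:
        pos = int(off * length)
        out[pos : pos + len(CTCF_SITE)] = CTCF_SITE
    return "".join(out)


def simulate_scenario(config: Optional[ScenarioConfig] = None) -> ScenarioBundle:
    """Build wild-type and mutant genomes for a tandem integration.

    The mutant carries ``n_full_copies + partial_fraction`` transgene copies
    tail-to-head at the insertion point, flanked by the target-site
    duplication; the truth record lists both host/transgene junctions, the
    tandem junction count, per-segment allele counts and the boundary bin.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    host_seq = random_sequence(cfg.host_chrom_length, rng)
    tg_seq = _make_transgene(cfg.transgene_length, rng)
    host = Genome({cfg.host_chrom: host_seq})
    sources = {cfg.transgene_name: Genome({cfg.transgene_name: tg_seq})}

    partial_len = int(round(cfg.partial_fraction * cfg.transgene_length))
    full = GenomicInterval(cfg.transgene_name, 0, cfg.transgene_length)
    components = [
        Component(source=cfg.transgene_name, interval=full) for _ in range(cfg.n_full_copies)
    ]
    if partial_len > 0:
        components.append(
            Component(
                source=cfg.transgene_name,
                interval=GenomicInterval(cfg.transgene_name, 0, partial_len),
            )
        )
    plan = RearrangementPlan(
        host_chrom=cfg.host_chrom,
        insertion_point=cfg.insertion_point,
        components=components,
        tsd_length=cfg.tsd_length,
    )
    mutant, liftover = build_mutant_genome(host, plan, sources)

    p, t = cfg.insertion_point, cfg.tsd_length
    core_len = cfg.n_full_copies * cfg.transgene_length + partial_len
    n_copies = cfg.n_full_copies + (1 if partial_len > 0 else 0)
    ctcf_in_full = len(CTCF_SITE_OFFSETS)
    ctcf_in_partial = sum(
        1
        for off in CTCF_SITE_OFFSETS
        if int(off * cfg.transgene_length) + len(CTCF_SITE) <= partial_len
    )
    truth = {
        "seed": cfg.seed,
        "insertion_point": p,
        "tsd_length": t,
        "core_length": core_len,
        "added_length": core_len + t,
        "partial_length": partial_len,
        "n_copies": n_copies,
        "junctions": [
            {
                "label": "left",
                "host_pos": p,
                "tg_pos": 0,
                "mutant_pos": p,
            },
            {
                "label": "right",
                "host_pos": p - t,
                "tg_pos": partial_len if partial_len > 0 else cfg.transgene_length,
                "mutant_pos": p + core_len,
            },
        ],
        "tandem_junctions_tail_to_head": max(0, n_copies - 1),
        # allele counts on the transgene axis for a hemizygous carrier on a
        # background with two endogenous copies of the source region
        "copy_segments": [
            {
                "start": 0,
                "end": partial_len,
                "allele_count": 2 + cfg.n_full_copies + 1,
            },
            {
                "start": partial_len,
                "end": cfg.transgene_length,
                "allele_count": 2 + cfg.n_full_copies,
            },
        ],
        "insert_ctcf_sites": cfg.n_full_copies * ctcf_in_full + ctcf_in_partial,
        "boundary_bin": p // cfg.hic.bin_size,
    }
    return ScenarioBundle(
        config=cfg,
        wildtype=host,
        sources=sources,
        mutant=mutant,
        plan=plan,
        liftover=liftover,
        truth=truth,
    )


def default_viewpoint(bundle: ScenarioBundle) -> GenomicInterval:
    """A TLA viewpoint in the middle of the first full transgene copy
    (mutant coordinates)."""
    cfg = bundle.config
    mid = cfg.insertion_point + cfg.transgene_length // 2
    return GenomicInterval(cfg.host_chrom, mid - 500, mid + 500)


def simulate_tla_reads(
    bundle: ScenarioBundle,
    viewpoint: Optional[GenomicInterval] = None,
    n_reads: Optional[int] = None,
    seed: Optional[int] = None,
) -> List[SimRead]:
    """Proximity-ligation chimeric reads around a viewpoint.

    Each read concatenates 1-4 restriction fragments of the mutant genome
    drawn from the viewpoint's neighbourhood; fragments end with the motif,
    so exactly one motif copy is retained at each ligation junction.  Truth
    tags record the source fragments and whether any fragment straddles a
    host/transgene junction.
    """
    cfg = bundle.config
    viewpoint = viewpoint or default_viewpoint(bundle)
    n_reads = cfg.n_tla_reads if n_reads is None else n_reads
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chrom_seq = bundle.mutant[viewpoint.chrom]
    motif = cfg.restriction_motif
    if motif not in chrom_seq:
        raise ValueError(f"restriction motif {motif!r} absent from the genome")
    frags = digest(chrom_seq, motif)
    if motif not in chrom_seq[viewpoint.start : viewpoint.end]:
        raise ValueError("viewpoint contains no restriction site")
    center = (viewpoint.start + viewpoint.end) // 2
    lo, hi = center - cfg.tla_neighborhood, center + cfg.tla_neighborhood
    nb = [f for f in frags if f[1] > lo and f[0] < hi]
    if not nb:
        raise ValueError("no fragments in the viewpoint neighbourhood")

    junction_pts = [j["mutant_pos"] for j in bundle.truth["junctions"]]
    reads: List[SimRead] = []
    for ridx in range(n_reads):
        k = int(rng.integers(1, cfg.max_ligation_fragments + 1))
        k = min(k, len(nb))
        picks = rng.choice(len(nb), size=k, replace=False)
        chosen = [nb[i] for i in picks]
        seq = "".join(chrom_seq[s:e] for s, e in chosen)
        spans = any(s < jp < e for s, e in chosen for jp in junction_pts)
        reads.append(
            SimRead(
                id=f"tla_{ridx:05d}",
                sequence=seq,
                tags={
                    "fragments": [(int(s), int(e)) for s, e in chosen],
                    "spans_junction": bool(spans),
                },
            )
        )
    return reads


def default_long_read_target(bundle: ScenarioBundle, flank: int = 2_000) -> GenomicInterval:
    """The inserted block plus a host flank on each side (mutant coords)."""
    lo, hi = bundle.liftover.insert_span
    return GenomicInterval(
        bundle.config.host_chrom,
        max(0, lo - flank),
        min(bundle.mutant.length(bundle.config.host_chrom), hi + flank),
    )


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitution/insertion/deletion noise (60/20/20 split of errors)."""
    if error_rate <= 0:
        return seq
    out = []
    bases = "ACGT"
    for ch in seq:
        r = rng.random()
        if r >= error_rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.6:  # substitution
            out.append(bases[int(rng.integers(0, 4))])
        elif kind < 0.8:  # insertion
            out.append(ch)
            out.append(bases[int(rng.integers(0, 4))])
        # else deletion: emit nothing
    return "".join(out)


def simulate_long_reads(
    bundle: ScenarioBundle,
    target: Optional[GenomicInterval] = None,
    n_reads: int = 30,
    read_length_range: Tuple[int, int] = (10_000, 35_000),
    error_rate: float = 0.05,
    off_target_fraction: float = 0.2,
    seed: Optional[int] = None,
) -> List[SimRead]:
    """Cas9-enrichment-style long reads from the mutant genome.

    On-target reads are released from within the target interval (length
    capped by the target), emulating fragments excised by flanking Cas9
    cuts; the remainder is sampled uniformly elsewhere.  Truth tags carry
    the error-free origin interval and strand.
    """
    cfg = bundle.config
    target = target or default_long_read_target(bundle)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chrom_seq = bundle.mutant[target.chrom]
    n = len(chrom_seq)
    reads: List[SimRead] = []
    for ridx in range(n_reads):
        length = int(rng.integers(read_length_range[0], read_length_range[1] + 1))
        on_target = rng.random() >= off_target_fraction
        if on_target:
            length = min(length, target.length)
            start = int(rng.integers(target.start, target.end - length + 1))
        else:
            start = int(rng.integers(0, n - length + 1))
        raw = chrom_seq[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _mutate(raw if strand == "+" else revcomp(raw), error_rate, rng)
        reads.append(
            SimRead(
                id=f"lr_{ridx:04d}",
                sequence=seq,
                tags={
                    "origin": (target.chrom, start, start + length),
                    "strand": strand,
                    "on_target": bool(on_target),
                },
            )
        )
    return reads


def simulate_depth(
    bundle: ScenarioBundle,
    window: int = 1_000,
    mean_cov: float = 100.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Windowed read counts along the transgene source axis for a test
    (transgene carrier) and control (allele count 2) sample.

    Test counts are Poisson with rate ``mean_cov * allele_count / 2``,
    control counts Poisson with rate ``mean_cov``.
    """
    cfg = bundle.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    length = cfg.transgene_length
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    mids = (starts + ends) / 2
    allele = np.empty(len(starts))
    for seg in bundle.truth["copy_segments"]:
        sel = (mids >= seg["start"]) & (mids < seg["end"])
        allele[sel] = seg["allele_count"]
    frac = (ends - starts) / window
    test = rng.poisson(mean_cov * allele / 2.0 * frac)
    control = rng.poisson(mean_cov * frac)
    return pd.DataFrame(
        {
            "start": starts,
            "end": ends,
            "test_count": test,
            "control_count": control,
            "true_allele_count": allele,
        }
    )


def simulate_hic(
    n_bins: int = 200,
    bin_size: int = 10_000,
    decay_alpha: float = -1.0,
    boundary_bins: Sequence[int] = (),
    insulation_factor: Union[float, Sequence[float]] = 1.0,
    mean_count: float = 50.0,
    seed: int = 0,
    noise: bool = True,
    chrom: str = "chrH",
) -> ContactMatrix:
    """Symmetric contact matrix with power-law decay and boundaries.

    Expected counts are ``mean_count * |i - j| ** decay_alpha`` (distance in
    bins, so ``mean_count`` is the expected adjacent-bin count), multiplied
    by the boundary's insulation factor once per boundary strictly between
    the two bins.  ``insulation_factor`` may be a scalar or one factor per
    boundary.  With ``noise=False`` the expectation matrix is returned.
    """
    if decay_alpha > 0:
        raise ValueError("decay_alpha must be <= 0")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    factors = (
        [float(insulation_factor)] * len(boundary_bins)
        if np.isscalar(insulation_factor)
        else [float(f) for f in insulation_factor]
    )
    if len(factors) != len(boundary_bins):
        raise ValueError("one insulation factor per boundary required")
    if any(not 0 < f <= 1 for f in factors):
        raise ValueError("insulation factors must be in (0, 1]")
    idx = np.arange(n_bins)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        mu = mean_count * np.where(d > 0, d, 1.0) ** decay_alpha
    for b, f in zip(boundary_bins, factors):
        left = idx < b
        crossing = left[:, None] ^ left[None, :]
        mu = np.where(crossing, mu * f, mu)
    if noise:
        rng = np.random.default_rng(seed)
        upper = rng.poisson(np.triu(mu))
        mat = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
        mat = mat.astype(float)
    else:
        mat = mu
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=mat)


def scenario_hic(
    bundle: ScenarioBundle, seed: Optional[int] = None, with_insertion_boundary: bool = True
) -> ContactMatrix:
    """Contact matrix matching the scenario: host-TAD boundaries plus
    (optionally) the insertion-site boundary at its configured factor."""
    cfg = bundle.config
    h = cfg.hic
    n_bins = cfg.host_chrom_length // h.bin_size
    boundaries = [bp // h.bin_size for bp in h.domain_breakpoints]
    factors = [h.domain_insulation_factor] * len(boundaries)
    if with_insertion_boundary:
        boundaries.append(bundle.truth["boundary_bin"])
        factors.append(h.boundary_insulation_factor)
    order = np.argsort(boundaries)
    return simulate_hic(
        n_bins=n_bins,
        bin_size=h.bin_size,
        decay_alpha=h.decay_alpha,
        boundary_bins=[boundaries[i] for i in order],
        insulation_factor=[factors[i] for i in order],
        mean_count=h.mean_count,
        seed=cfg.seed if seed is None else seed,
        chrom=cfg.host_chrom,
    )


def random_fragments(
    start: int, end: int, mean_length: int, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Non-overlapping restriction-fragment-like intervals tiling [start, end)."""
    cuts = [start]
    pos = start
    while pos < end:
        pos += max(50, int(rng.exponential(mean_length)))
        cuts.append(min(pos, end))
    return list(zip(cuts[:-1], cuts[1:]))


def simulate_4c(
    viewpoint_pos: int,
    fragment_boundaries: Sequence[Tuple[int, int]],
    decay_rate: float = 2e-5,
    boundary_positions: Sequence[int] = (),
    insulation_factor: float = 1.0,
    mean_score: float = 200.0,
    seed: int = 0,
    noise: bool = True,
    chrom: str = "chrH",
    genotype: str = "",
) -> FourCProfile:
    """Per-fragment 4C scores decaying exponentially with distance from the
    viewpoint, attenuated by ``insulation_factor`` once per boundary between
    fragment and viewpoint."""
    if not 0 < insulation_factor <= 1:
        raise ValueError("insulation factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    starts = np.array([f[0] for f in fragment_boundaries])
    ends = np.array([f[1] for f in fragment_boundaries])
    mids = (starts + ends) / 2
    rate = mean_score * np.exp(-decay_rate * np.abs(mids - viewpoint_pos))
    for b in boundary_positions:
        crossing = (mids - b) * (viewpoint_pos - b) < 0
        rate = np.where(crossing, rate * insulation_factor, rate)
    scores = rng.poisson(rate).astype(float) if noise else rate
    df = pd.DataFrame({"start": starts, "end": ends, "score": scores})
    vp = GenomicInterval(chrom, viewpoint_pos, viewpoint_pos + 1)
    return FourCProfile(viewpoint=vp, fragments=df, genotype=genotype)


def simulate_ct(
    allele_counts: Dict[str, Dict[str, float]],
    reference_target: str = "reference",
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    groups: Optional[Dict[str, str]] = None,
    seed: int = 0,
    baseline: float = 25.0,
) -> pd.DataFrame:
    """Raw qPCR Ct records: ``Ct = baseline(target) - log2(copies) + noise``.

    The reference target is fixed at allele count 2 for every sample.
    Returns a tidy table (sample, group, target, replicate, ct).
    """
    rng = np.random.default_rng(seed)
    groups = groups or {}
    targets = sorted({t for d in allele_counts.values() for t in d} | {reference_target})
    # target-specific amplification baselines, fixed across samples
    offsets = {t: float(rng.uniform(-2.0, 2.0)) for t in targets}
    rows = []
    for sample in sorted(allele_counts):
        counts = dict(allele_counts[sample])
        counts[reference_target] = 2.0
        for target in targets:
            if target not in counts:
                continue
            copies = counts[target]
            if copies <= 0:
                raise ValueError("allele counts must be positive")
            for rep in range(n_replicates):
                ct = (
                    baseline
                    + offsets[target]
                    - np.log2(copies)
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                )
                rows.append(
                    {
                        "sample": sample,
                        "group": groups.get(sample, ""),
                        "target": target,
                        "replicate": rep,
                        "ct": float(ct),
                    }
                )
    return pd.DataFrame(rows)
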