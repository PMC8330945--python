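# Methods

`tgmap` implements the computational workflow for characterizing a random
transgene integration at base-pair resolution and quantifying its effect on
local chromatin topology. Every stage can be exercised against synthetic
data with known ground truth; this note records the models, the parameters
that matter, the numerical choices, and what the synthetic results do and do
not demonstrate about real data.

## The integration model

An integration is described declaratively (`RearrangementPlan`): an ordered
list of insert components (full transgene copies, a partial copy, literal
sequence), each forward or reverse-complemented, inserted at one host
position `p` with a target-site duplication (TSD) of `t` bp. The mutant
chromosome is

```
host[0:p] + components + host[p-t:p] + host[p:]
```

so the duplicated host segment flanks the insert core on both sides and the
left host/insert junction lies between the two duplicate copies. Coordinates
convert between wild-type and mutant axes through a piecewise-shift liftover
that is bijective outside the inserted block.

Coordinate convention: positions are 0-based, half-open. Browser-style
region strings are parsed verbatim with length = end − start. This is a
deliberate quirk: the characterized duplication `chr10:97019222-97019824` is
reported as 602 bp, which is end − start, not the 603 bp of the standard
1-based inclusive reading; the parser follows the reported arithmetic so
printed coordinates and printed lengths stay consistent.

The worked-example reconstruction (`casestudy.build_case_study`) rebuilds
the characterized line from its printed parameters — 63,812 bp total
inserted block, 602 bp TSD, a 45 kb fosmid (three same-orientation CTCF
sites) plus a partial second copy reaching past the first CTCF site — on a
toy host, and measures duplication length (602), transgene-derived insert
span (63,210 bp = 63.2 kb) and insert CTCF-site count (4) on the constructed
genome rather than asserting stored constants.

## Synthetic data generator

`simulate_scenario` draws a random host chromosome (default 2 Mb) and
transgene unit (default 40 kb with CTCF-like motifs planted at fixed
relative offsets), then builds the mutant as one full copy plus a 0.55
partial copy tail-to-head with a 600 bp TSD at 1.2 Mb — a small-scale
re-creation of the characterized configuration. All generators use one
explicitly seeded NumPy stream and are byte-identical under a fixed seed.
The default scenario (seed 42) *is* the study condition: its truth record
(junction coordinates, copy counts, boundary bin) scores every downstream
stage without re-deriving anything from sequence.

- **TLA reads** — the mutant is digested at the restriction motif (CATG,
  NlaIII-style, cut after the motif so each fragment ends with it); each
  read concatenates 1–4 fragments drawn uniformly from a ±50 kb viewpoint
  neighbourhood, leaving exactly one motif copy per ligation junction.
  Reads are whole ligation products; sampling is not proximity-weighted
  beyond the neighbourhood cut-off.
- **Long reads** — 10–35 kb reads released from within a target interval
  (emulating flanking Cas9 cuts), plus an off-target fraction sampled
  uniformly; substitution/insertion/deletion noise at 60/20/20 of the error
  rate (default 5%).
- **Depth** — per-window Poisson counts along the transgene axis with rate
  ∝ allele count/2 for the carrier (a hemizygous insertion on a
  two-endogenous-copy background: 4 alleles over the doubly-present prefix,
  3 over the remainder) and allele count 2 for the control.
- **Hi-C** — expected counts `mean_count · |i−j|^alpha` (distance in bins,
  `mean_count` = expected adjacent-bin count), multiplied by a boundary's
  insulation factor once per boundary strictly between the bins, then
  Poisson-sampled symmetrically. The log-log slope is invariant to the
  distance unit, so fitting recovers `alpha` regardless of bin size. Default
  bin 10 kb, alpha −1.0, mean 50. The default domain layout nests the
  insertion boundary between two strong (factor 0.3) host-TAD boundaries 22
  and 10 bins away — the studied proportions (a ~1.2 Mb TAD split ~70/30 by
  the insertion) at bin-count scale.
- **4C** — per-fragment Poisson scores decaying exponentially with distance
  from the viewpoint, attenuated by the insulation factor per intervening
  boundary.
- **qPCR** — `Ct = baseline(target) − log2(alleles) + N(0, sd)`, reference
  target fixed at two alleles.

Not modelled: mappability and GC bias, PCR duplicates, realistic error
profiles, proximity-weighted ligation, trans contacts, ploidy. Passing
synthetic suites therefore demonstrates correctness of the *analysis logic*
(windowing, splitting, consensus, estimation, statistics), not robustness to
the artefacts of real libraries.

## Read mapping

A deterministic exact-k-mer aligner (`align`) stands in for production
mappers, which would be disproportionate for toy genomes. Anchors (default
k = 21) seed either full-length ungapped verification (≤ 2% mismatches;
"end-to-end") or maximal exact-match extension with the remainder clipped
("local"). Instead of a probabilistic mapping quality, a boolean `unique`
flag (placement supported by a k-mer occurring once in the reference) plays
the role that a MAPQ > 30 filter plays on real data. Ties break to the
lexicographically smallest (chromosome, position), making all downstream
results reproducible. Local extension is exact-match, which is what gives
junction coverage its base-pair-sharp edges on error-free reads.

## TLA integration mapping

1. **Window scan** — unique end-to-end host coverage summed over 1 Mb
   windows; the maximal window (exclusion list masked, ties to the lowest
   coordinate) is the candidate integration site.
2. **Motif splitting** — reads failing end-to-end mapping are split at
   CATG (motif retained with the upstream piece, matching religation
   chemistry); pieces ≤ 25 bp are discarded, as are pieces mapping
   end-to-end to either the host or the transgene (digestion/religation
   products). Survivors are candidate hybrid-junction pieces.
3. **Breakpoint steps** — local mapping of survivors yields host coverage
   whose adjacent-base steps exceeding 0.8 of the local maximum are
   reported. The local maximum is searched within ±250 bp: the locality
   must be narrower than the TSD spacing (~600 bp), or the stronger
   junction's coverage masks the weaker one. The 0.8 fraction is a free
   parameter chosen so a clean step is always called and flat Poisson noise
   is not.
4. **Junction consensus** — clipped pieces grouped by (anchored reference,
   junction-adjacent coordinate, clip side); per-position majority consensus
   of the overhangs (ties alphabetical), then the consensus is locally
   mapped to identify the partner side. Junction coordinates are the last
   matching base of the upstream side and the first of the downstream side;
   calls need support ≥ 2 by default, and reciprocal discoveries (host- and
   transgene-anchored) merge when within 1 bp. Microhomology at a junction
   makes the exact cut-point ambiguous by its length; recovered coordinates
   are accurate to ±1 bp on the default scenario.
5. **Tandem configuration** — reads are cut at the motif and the pieces
   mapped end-to-end onto a four-copy multi-orientation concatemer
   (`-> -> <- ->`); pieces covering the copy1|copy2, copy2|copy3 and
   copy3|copy4 seams by ≥ 21 bp on both sides count as tail-to-head,
   tail-to-tail and head-to-head support respectively. No uniqueness filter
   is applied: head-to-head and tail-to-tail junction sequences are their
   own reverse complements, so a spanning read always has two mirror
   placements around the same seam; specificity comes from the span
   requirement (within-unit reads never span a seam). Note that junction
   attestation requires the unit's terminal restriction fragments to be at
   least the flank length: a cut site falling within 21 bp of the unit
   boundary makes two-sided 21 bp flanks impossible for any read depth.

## Long-read validation

Dot-plot anchors are exact 20-mers sampled every 5 bp of the read and kept
only when unique in the reference; both read orientations are scanned and
the richer one reported (nanopore reads are unoriented). A read's verdict
against a candidate reconstruction comes from its longest
increasing anchor chain: diagonal offsets between consecutive chain anchors
beyond 50 bp + 1% of the anchor gap are breaks (the gap-proportional term
absorbs indel drift across anchor-free stretches — stretches that arise
legitimately where the reconstruction itself duplicates sequence and no
k-mer is unique). `supported` = no breaks and ≥ 90% of anchors on the
chain; fewer than 5 anchors = `uninformative` rather than rejection, since
a read confined to an internally duplicated block cannot testify either
way. Enrichment is the on-target base fraction divided by the target's
genome share, computed from generator truth tags.

## Copy number and expression

Delta-delta-Ct: replicates further than 0.5 cycles from their median are
discarded (the outlier rule is configurable; only that outliers *are*
discarded is inherited from practice), ΔCt is taken to the reference locus,
ΔΔCt to the calibrator-group mean, and allele counts are `2^(−ΔΔCt) · 2`,
reported unrounded. Depth-based estimation uses the `(test/control)·2`
windowed ratio (windows with control < 10 masked) summarised over a segment
by the median with a 199-resample bootstrap interval — a deliberately simple
segment estimator; a full maximum-likelihood multi-state caller is a project
of its own and out of scope. Relative expression uses the same ΔCt
referencing with fold change `2^−(meanΔCt_b − meanΔCt_a)` and Welch's
unequal-variance t-test.

## Contact analytics

- **Balancing** — iterative proportional fitting to equal row sums (1e-5
  relative tolerance, ≤ 500 sweeps), bins with < 10 total counts masked.
- **Distance decay** — `log c(d)` vs `log d` by weighted least squares on
  per-distance mean contacts with weight = total observed count at that
  distance (the inverse variance of the log-mean under Poisson counting);
  zero-count distances are dropped. An unweighted fit over all distances
  would be dominated by the heavily biased log of near-zero long-range
  means; the weighting makes the estimate exact on noise-free power-law
  matrices and accurate to ~0.003 (mean |error|, 20 seeds, 200 bins, mean
  count 50) on Poisson-sampled ones.
- **Insertion rescaling** — to compare a wild-type map against a mutant map
  whose coordinates contain an extra `delta` bp, wild-type contacts whose
  bin midpoints straddle the insertion point are multiplied by
  `((d + delta)/d)^alpha`. The transformation is isolated in one function
  so alternative interpretations can be swapped in.
- **Insulation** — per-bin mean contact in the w×w diamond crossing the
  bin's left edge, log2-normalised to the chromosome-wide mean (per
  chromosome, not per region). Defined where the full diamond fits.
- **Boundary calling** — per window size (defaults 6/8/12/20 bins, the
  240/320/480/800 kb ladder at 40 kb bins expressed as bin counts), local
  insulation minima with depth ≥ 0.1 (log2) below the shallower flanking
  maximum (searched within one window each side) are tested by a one-sided
  Mann–Whitney rank comparison of the crossing diamond against the diamonds
  at the two flanking maxima, Bonferroni-corrected over all minima examined.
  Calls merge across windows (±1 bin) and carry the smallest detecting
  window. A known limitation: because the generator applies insulation as a
  single multiplicative factor to every crossing pair, the test's power
  *increases* with window size (more diamond values, same relative shift),
  so weak boundaries tend to be found at the larger windows. Real nested
  chromatin shows the opposite pattern — weak sub-TAD boundaries visible
  only at small windows — which this scale-free contact model cannot
  express; six statistic variants (raw / observed-expected ratio /
  per-diagonal z values × fixed vs flank-maxima comparison diamonds) were
  evaluated and none reverses the monotonicity without inflating the
  false-call rate. The shipped design is the one with zero false calls on
  20 boundary-free matrices and 20/20 recovery of a factor-0.5 boundary.
- **Differential box** — `fc = (mean(mut) − mean(wt))/mean(wt)` over the
  bin-pair rectangle between two intervals, two-sided Mann–Whitney U
  (mid-ranks, continuity correction) over unmasked bin values.
- **4C** — scores normalised to the mean of fragments within ±10 Mb of the
  viewpoint; the viewpoint fragment ±1 fragment is excluded from the
  normalisation mean (the exclusion radius is this package's choice).
  Smoothing is an 11-fragment running mean, window shrinking symmetrically
  at the edges. Segment fold changes normalise per-genotype segment sums to
  the host-TAD sum, with explicit exclusion intervals (insert, duplication,
  viewpoint) left out of all sums.

## Problem sizes

Test and acceptance runs use a 2 Mb host, 40 kb transgene, 2,000 TLA reads,
30 long reads, 200-bin contact matrices at 10 kb bins and 20-seed replicate
suites — small enough for the whole suite to complete in well under a minute
per stage while preserving the structure of the full-scale analysis.
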