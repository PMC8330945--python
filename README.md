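# tgmap

Base-pair mapping of transgene integrations and quantification of their
chromatin-boundary effects.

Random transgenesis inserts a construct — often as a tandem concatemer with
a target-site duplication (TSD) — at an unknown genomic position. Before any
statement can be made about what the insertion does to its new neighbourhood
(for instance, whether an ectopic CTCF-site cluster splits the host
topologically associating domain, TAD), the integration has to be resolved
at base-pair precision: where it landed, how many copies, in which
orientation, with what duplication. `tgmap` implements that workflow for
people analysing targeted locus amplification (TLA), Cas9-targeted nanopore
(nCATS-style), qPCR, windowed-depth, Hi-C and 4C data — together with a
ground-truthed synthetic-scenario generator so every stage is testable
end to end.

## What it computes

**Integration mapping (TLA).** Chimeric proximity-ligation reads are scanned
for the 1 Mb window of maximal unique end-to-end coverage; reads failing
end-to-end mapping are split at the NlaIII motif (CATG, retained with the
upstream piece), pieces mapping cleanly to either reference are discarded,
and the surviving hybrid pieces are locally mapped. Coverage steps mark
candidate breakpoints; majority consensus of clipped overhangs, locally
remapped, yields `JunctionCall`s with base-pair coordinates for both sides.
A four-copy multi-orientation concatemer (`-> -> <- ->`) counts reads
supporting tail-to-head, tail-to-tail and head-to-head tandem junctions.

**Reconstruction and validation.** A `RearrangementPlan` (components,
orientations, TSD) builds the mutant genome,
`host[0:p] + insert + host[p-t:p] + host[p:]`, with a liftover map between
axes. Long reads are validated against the reconstruction by unique-20-mer
dot-plot anchors (5 bp stride): one monotone diagonal supports it, offset
breaks reject it, and on-target enrichment is measured as the on-target base
fraction over the target's genome share.

**Copy number.** ΔΔCt allele counts `2^(−ΔΔCt)·2` from Ct tables (reference
locus, calibrator group, outlier-trimmed replicates), and windowed
`(test/control)·2` depth ratios summarised per segment by median with a
bootstrap interval. RT-qPCR relative expression with Welch's t-test.

**Contact analytics.** Matrix balancing (iterative proportional fitting),
power-law distance-decay fits (`log c(d) = α·log d + c0`, count-weighted),
insertion-aware rescaling of wild-type maps by `((d+Δ)/d)^α`, diamond
insulation scores, multi-window boundary calling (insulation minima +
rank-sum test + Bonferroni, smallest detecting window annotated),
differential inter-domain boxes `fc = (mean(mut)−mean(wt))/mean(wt)` with
Mann–Whitney p-values, and 4C profile normalisation (±10 Mb flank mean),
11-fragment smoothing and per-segment fold changes.

## Worked example

```python
from tgmap import *

# reconstruction arithmetic of the characterized line, from its printed
# parameters (63,812 bp inserted block, chr10:97019222-97019824 duplication)
cs = build_case_study(seed=0)["summary"]
print(f"duplication: {cs.duplication_length_bp} bp")
print(f"insert span: {cs.insert_span_kb} kb")
print(f"CTCF sites in insert: {cs.insert_ctcf_sites}")

# synthetic integration scenario (2 Mb host, 1 full + 0.55 partial copy,
# 600 bp TSD at position 1,200,000) analysed blind by the TLA pipeline
bundle = simulate_scenario()
reads = simulate_tla_reads(bundle)            # 2,000 ligation products
result = run_tla(reads, bundle.wildtype, bundle.sources["transgene"],
                 fosmid_sequence=bundle.transgene_sequence)
print("candidate window:", result.report.candidate_window)
for j in result.report.junctions:
    print(f"  {j.side_a[0]}:{j.side_a[1]} -> {j.side_b[0]}:{j.side_b[1]} "
          f"(support {j.support})")
print("tandem:", result.report.tandem_counts)

# contact analytics on simulated matrices
m = simulate_hic(n_bins=200, decay_alpha=-0.42, mean_count=50, seed=1)
print(fit_distance_decay(m).summary())

wt  = simulate_hic(n_bins=200, decay_alpha=-1.0, mean_count=50, seed=42)
mut = simulate_hic(n_bins=200, decay_alpha=-1.0, boundary_bins=[100],
                   insulation_factor=0.5, mean_count=50, seed=43)
box = (GenomicInterval("chrH", 600_000, 1_000_000),
       GenomicInterval("chrH", 1_000_000, 1_400_000))
print(differential_box(mut, wt, box).summary())
```

prints

```
duplication: 602 bp
insert span: 63.2 kb
CTCF sites in insert: 4
candidate window: chrH:1000000-2000000
  chrH:1199999 -> transgene:0 (support 19)
  transgene:22000 -> chrH:1199401 (support 11)
  transgene:39999 -> transgene:0 (support 14)
tandem: {'tail_to_head': 14, 'tail_to_tail': 0, 'head_to_head': 0}
distance-decay fit: alpha = -0.419, R = -0.998, 198 distance points over 20000-1990000 bp
differential box: fc = -0.504 (-50.4%), Mann-Whitney p = 2.98e-58, 1600 bin pairs
```

Reading the junction calls against the scenario's truth: the left breakpoint
joins the last host base 1,199,999 to the transgene start (exact); the right
breakpoint joins the partial copy's end (~22,000) back to the duplication
start 1,199,400 (±1 bp — one base of microhomology at the junction makes the
exact cut point ambiguous); the transgene→transgene call is the internal
tail-to-head fusion of the full and partial copies, corroborated by the
concatemer test (14 tail-to-head pieces, zero for the other orientations).
The decay fit recovers the simulated exponent −0.42, and the differential
box recovers the simulated 50% loss of inter-domain contacts.

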