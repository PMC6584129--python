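# Methods

## Compositional definitions

Two window statistics characterize AT-richness against a high-GC
background. An **AT-rich segment** is a 20-nt window containing strictly
more than 50% A/T; since 10 of 20 is exactly half, the threshold is ≥11 of
20. An **AT-rich core** is any 6 consecutive nucleotides of which ≥5 are
A/T. Both are exposed as a configurable `(window_len, min_at)` pair
(`ScanConfig`), defaulting to 20/11 and 6/5.

For each sequence the scanner reports *overlapping* counts (every
qualifying start position) and *maximum non-overlapping* counts. The
disjoint count is computed by earliest-end greedy selection; because all
windows of one scan share a single length, earliest-end order coincides
with start order and the greedy solution is the exact maximum independent
set of qualifying windows (the classic interval-scheduling argument). Both
counts are always emitted because published "non-overlapping stretch"
counts do not state which convention applied to baseline segments; tests
verify greedy optimality against an exact dynamic program.

**N handling.** N counts as neither A/T nor G/C. GC content is
(G+C)/(A+C+G+T) with N excluded from numerator and denominator, undefined
(an error) for empty or all-N input. A window containing N can still
qualify if its A/T count alone meets the threshold — conservative toward
the AT criterion, since N never helps a window qualify.

**Genome baseline.** `sample_baseline_segments` draws segments uniformly
over all valid start coordinates, annotation-blind, seeded. The reference
design — 15 segments of 500 bp and 15 of 1000 bp — is the default in the
analysis driver.

## Coordinates, clusters, regions

All internal coordinates are 1-based inclusive (GFF convention); BED input
is converted at the boundary (start+1). Cluster membership follows the
cluster-table convention: a cluster is the inclusive *locus-index* range
from its first to its last gene (e.g. a 12-locus ectoine cluster), not a
genomic interval; genes whose IDs do not follow the `prefix_digits` form
need explicit membership lists (`member_mode="explicit"`). The
left-arm/core/right-arm partition of the linear chromosome is
user-supplied configuration — arm/core limits are a published
chromosome-biology annotation, not derivable from sequence — and is
validated to be contiguous, ordered and covering.

## Binding-site annotation

Sites are kept when q < 0.01 (strict, matching "less than 0.01"). A site
associates with a gene when it intersects the gene body
(`overlaps_cds`) and/or the strand-aware upstream interval of
`upstream_window` nt ending at the gene's 5′ end (`upstream`). "Immediately
upstream" is unquantified in the source analyses; the default window is
300 nt, chosen as a typical bacterial promoter/UTR scale, and
configurable. A site between divergent promoters can associate with both
flanking genes. Region assignment uses the site midpoint (sites are small
relative to regions); a midpoint exactly on a region boundary belongs to
the leftward interval. A site is "associated with transcriptional change"
iff any associated gene passes the DE filter. Per-region summaries report
counts, change fractions, and mean widths by change status, with empty
groups reported as absent (NaN), never zero.

## Differential expression and enrichment

RPKM = count / ((length/1000)·(library/10⁶)). The significance filter is
strict in both thresholds: max(fc, 1/fc) > 4 **and** q < 0.01, so fc = 4.0
or q = 0.01 fail; both directions are retained. When fold change must be
derived from expression means, a pseudocount of 1.0 RPKM is added to both
(silenced clusters have wild-type RPKM near zero; the pseudocount keeps
ratios finite and is configurable). q-values are consumed as given —
recomputing the upstream DE model's adjustment is out of scope.

Cluster summaries count significant members over the locus span (or an
explicit list) and report pct_up = 100·n_up/n_members rounded to two
decimals. The enrichment test is the one-sided upper binomial tail
P(X ≥ k) under the null that each of the n DE genes falls in a cluster
with probability p₀; it is evaluated with the regularized incomplete beta
(scipy's `binom.sf`), verified in tests against exact rational-arithmetic
summation to 10⁻¹⁰ relative error. p₀ is supplied or reconstructed as
(union of cluster locus spans)/(total loci); overlapping spans are merged
so shared loci count once. For the packaged reference table the union is
1021 loci; over the 7455-locus chromosome p₀ ≈ 0.1370. The published
per-cluster percentage denominators are not all consistent with inclusive
spans (one cluster prints 93.33%, implying 15 genes where the span holds
16 — predicted cluster boundaries are acknowledged to be generous);
span-count and explicit-count modes both exist for this reason, and the
worked-row checks use the two clusters whose printed denominators equal
their spans.

## Variant design

`raise_gc` performs only A/T→G/C substitutions. The substitution budget is
`round(target·L) − current_GC_count` over non-N positions; if the nearest
attainable GC differs from the target by more than 0.005 (possible only
for very short sequences) or the budget exceeds the eligible positions,
the design errors out naming the deficit. In `disrupt_cores` mode each
substitution greedily targets the position covered by the most surviving
qualifying core hexamers (ties leftmost, coverage recomputed after each
hit); once no core survives, the remaining budget is spent on randomly
chosen eligible A/T positions. In `spare_cores` mode only A/T positions
covered by *no* qualifying core are eligible — and since A/T→G/C
substitutions outside all qualifying hexamers can never create or destroy
a qualifying hexamer, every core survives by construction (asserted in
tests). The replacement letter is G or C by seeded coin flip; the entire
design is deterministic under (sequence, spec). Lowering GC is not
supported: the experimental series only raised it.

## Synthetic data

Generators plant known truth so recovery is checkable end to end:

* **Chromosome**: i.i.d. bases at P(G or C) = 0.724 (the reference
  chromosome average), islands i.i.d. at their AT fraction (default 0.55),
  each island optionally stamped with one all-A/T hexamer at its centre so
  a core is guaranteed. i.i.d. composition is deliberately simpler than a
  real genome's patchy heterogeneity; this is exactly why the published
  baseline counts (e.g. most random 500-bp segments lacking an AT core)
  are *not* value-level targets here — an i.i.d. 72.4% GC sequence carries
  more scattered AT runs than a real high-GC chromosome with compositional
  autocorrelation. Passing recovery tests demonstrates correctness of the
  pipeline's logic, not realism of the background model.
* **Annotation**: genes packed left-to-right with random lengths
  (≈850 nt mean) and gaps, locus numbering strictly increasing with
  coordinate; clusters as disjoint blocks of consecutive loci (default
  25 × 40 = 1000 cluster loci among 8000); regions as quarter/half/quarter.
* **DE tables**: per-gene Bernoulli significance at 0.15 inside clusters
  vs 0.04 outside (the reference study's ~15% vs <5% contrast); planted
  genes draw fc log-uniform in (4.5, 900) — 10% inverted to repression —
  and q log-uniform below 0.01; all others draw sub-threshold values, so
  the planted set equals the filter output exactly.
* **Sites**: one per island with bounds jittered by ≤10% of island length
  and q below threshold, plus uniform noise sites with uniform q.
* **Volatiles**: per-compound log10 intensity Normal(μ, 0.25) with
  μ ~ U(4, 7); shifted compounds displaced by `shift_sd`·σ in one strain
  group (alternating); a sterile-medium group at a lower baseline is
  carried for display only.

The full-scale scene (8 Mb, 8000 loci, ~220 islands/sites) generates in
about a second; tests and drivers use scaled-down scenes (scale 0.02–0.1)
where full scale adds nothing to the property under test.

## Volatile statistics

Per compound: zeros are imputed as half the compound's smallest positive
intensity (the handling is unstated in the source protocol; half-minimum
is the common metabolomics convention), then log10, mean-center, unit
scale (population sd). Zero-variance or <2-finite compounds are excluded
from testing. The Mann–Whitney U test is two-sided, exact (full
permutation null) when the combined sample size is ≤12 with no ties,
otherwise normal approximation with continuity and tie corrections.
Because the test is rank-based and the per-compound transform is strictly
monotone, p-values are identical on raw and transformed data; the
transform matters for display. BH adjustment is the standard step-up;
selection is adjusted p < α (default 0.05) with direction by group
medians.

**Known limitation — the exact-test floor.** With 6 samples per group the
smallest attainable two-sided exact p is 2/C(12,6) = 2/924 ≈ 0.00217.
Under BH across 200 compounds at α = 0.05, any selection requires at
least nine p-values at that floor, i.e. at least nine compounds with
perfect group separation. At a planted 3-σ shift, perfect separation has
probability ≈0.7 per compound, so the selected set is bimodal across
seeds: usually either empty or nearly all ten planted compounds. This is
an intrinsic discreteness of exact rank tests at small n interacting with
FDR control, not an implementation artifact; studies with hundreds of
compounds and n ≈ 6 replicates sit exactly at this edge.

## Pipeline and CLI

`run_pipeline(RunConfig)` validates paths and thresholds before any
computation, runs whichever stages have inputs, writes one TSV per section
plus a `manifest.json` of all parameters, and is byte-reproducible for a
fixed config (verified in tests). The `lsr2tools` CLI exposes each stage
as a subcommand with the reference thresholds as defaults; exit codes
distinguish usage (2), parse/validation (3) and computation (4) errors.
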