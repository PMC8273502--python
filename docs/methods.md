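# Methods

## Problem and model

In a ZZ/ZW system the W chromosome is restricted to females. If females and
males are sequenced as two pools and mapped to a female (W-containing)
assembly, a W-specific sequence is covered by roughly half of the female
pool's haplotypes — haploid depth, ~0.5 after diploid normalization — and
by none of the male pool's, up to mismapping. The analyses here turn that
asymmetry into calls at three resolutions: base-pair runs (coverage),
variant sites (pooled allele counts) and whole contigs (mean coverage), and
validate a resulting marker by concordance with phenotypic sex.

## Coverage normalization

Each pool is normalized independently by its *diploid coverage peak*: the
mode of the histogram of per-bp depth weighted by base pairs (the depth bin
holding the most sequence). Depth-0 base pairs are excluded — unsequenced
or absent regions would otherwise dominate fragmented references — and
ties resolve to the lower depth, a conservative choice: a lower peak
inflates normalized values, making the `> 0.3` floor easier and the result
set no smaller. Bin width defaults to 1 read. Note that a Poisson depth
distribution with integer mean m has exactly tied modes at m−1 and m, so
the estimator legitimately returns either on sampled data; all downstream
thresholds are ratios, which a one-read peak shift changes by ~2.5% at 40×.

## Region calling

With both tracks in diploid units the per-bp predicate is

    opposite <= max_opposite   AND   target > min_target

with defaults `max_opposite = 0` (inclusive, so exact zero passes) and
`min_target = 0.3` (strict). Maximal passing runs are merged transitively
when separated by at most `merge_gap = 30` bp — the distance convention of
`bedtools merge -d`, verified against bedtools in the test suite — and
merged blocks are kept when at least `min_len = 160` bp long. The size
filter is inclusive (`>= 160`); a strict variant is exposed as
`min_len_strict` because "larger than" readings differ. Merging precedes
the size filter, so sub-threshold fragments can combine into a reported
region; region means are computed over the merged extent with bridged-gap
base pairs counting as depth 0 for uncovered positions (hence a merged
region's mean opposite coverage may exceed `max_opposite` even though every
*passing* bp satisfied it).

The floor applies per base pair, not to block means: the implementation
mirrors an awk-style filter on bedgraph lines, and per-bp filtering is the
stricter, more reproducible reading. Chromosomes are processed
independently; there is no cross-chromosome merging.

The swapped-sex control reruns the identical procedure with pool roles
exchanged. It is the specificity control: thresholds that admit hits in
both directions are not detecting sex linkage but coverage noise.

## Variant screen and clustering

Cutoffs act on alternate-allele-supporting reads (defaults: ≥ 10 in the
target pool, ≤ 0 in the opposite pool). Site depth is deliberately not
used: a locus present in both sexes still accumulates reference reads in
both pools, so only the alt-read asymmetry is informative. Screened
variants are chained per chromosome by single linkage with a 4000 bp
maximum inter-variant gap, distance measured between successive start
positions (INDEL span ignored). Clusters are ranked by member count with
genomic order as the deterministic tie-break.

## Contig classification

A contig is female-specific when its length-weighted mean normalized female
coverage lies in the haploid band [0.3, 0.7] and its male coverage is at
most 0.1; male-specific symmetrically; otherwise unassigned. No published
numeric band exists for "putative haploid" and "spurious" coverage, so the
band is centred on the theoretical 0.5 with generous Poisson slack and all
three thresholds are exposed. Because `max_spurious < haploid_low`, the two
specific labels are mutually exclusive by construction.

## Concordance testing

For a 2×2 table (a, b; c, d) of marker call × sex,

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / (R1 R2 C1 C2),   p = P(chi2_1 >= chi2)

The Yates term is clamped at zero so near-balanced tables report chi2 = 0,
p = 1 rather than a spurious signal. A zero marginal (a species with only
one sex, or only one call outcome) leaves the statistic undefined and
raises rather than returning NaN. The implementation is cross-checked
against `scipy.stats.chi2_contingency(correction=True)` property-wise, and
reproduces all six published validation designs to their printed
significant figures (smallest p = 5.352 × 10⁻¹³ for 28 concordant females
and 28 concordant males).

## Synthetic scenario generator

The generator emulates what the analysis consumes, not the sequencing
process: depth is drawn per base pair, reads are never simulated. Defaults
are the study conditions the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| genome_length | 1 Mb | Z backbone length |
| w_region_length / start | 16 kb at 500 kb | W-specific insertion in the female assembly |
| female_peak / male_peak | 42× / 37× | diploid Poisson depth per pool |
| mismap_rate | 5 × 10⁻⁴ /bp | rate of spurious male-pool runs inside the W region |
| spurious_match_mean_len / max_len | 80 / 200 bp | geometric run lengths, capped |
| n_w_linked_snps | 27 in a 16 kb window | W-linked variants, window 100 kb downstream of the insertion |
| w_allele_fraction | 0.25 | expected W-allele fraction among pooled haplotypes |
| n_background_snps | 1000 | shared polymorphisms, one frequency for both pools |
| contigs | 1067 W-private (~617 bp mean) + 500 autosomal | coverage-summary fixtures |
| genotype designs | six published tables | e.g. 18 positive females / 18 negative males |

Depth is Poisson(peak) on diploid sequence, Poisson(peak/2) for the female
pool across the W insertion, and 0 for the male pool there except mismap
runs (depth 1 + Poisson(2)). Mismapping is modelled as short contiguous
runs rather than independent base pairs because that is the footprint
repeat-induced mismapping leaves — isolated single-bp noise would be
healed or removed by the merge/size filters and would exercise nothing.
W-linked variant sites draw female alt reads as Binomial(depth, 1/4) —
one W among four pooled haplotypes at a Z/W-shared site in a tetraploid
female pool — with zero male alt reads; at the default 42× this leaves the
per-site probability of passing the ≥ 10-read screen near 0.6, so roughly
16–19 of the 27 planted sites survive in a typical seed while the top
cluster still recovers the planted window essentially always. The SNP
window sits 100 kb downstream of the insertion (a separation chosen to fit
the 1 Mb genome) so the pipeline's cluster-versus-region cross-reference
has a known planted answer. All randomness descends from one integer seed
through tagged child generators; identical seeds give byte-identical files.

What the generator does **not** model — and what passing tests therefore do
not show about real data: repeat content and mapping ambiguity (real
W regions can be ~40% repetitive, which fragments the coverage signal far
more than Poisson noise), reference errors, sequencing/base quality,
library bias, polyploid dosage beyond the single W haplotype fraction, and
pseudo-autosomal recombination gradients. Genome-scale results (multi-Mb
coordinates, 150 Gbp read sets) are structurally accepted but not
re-derived; recovery claims hold for the planted-signal conditions above.

## Numerical and scale choices

Tracks are stored as run-length interval arrays (0-based half-open
everywhere; VCF shifted on ingestion). The region caller works on the
two-track union partition with prefix sums, and is required by tests to be
interval-for-interval identical to a literal per-bp brute force on ~1000
randomized pairs; recovery tests use a 1 Mb genome across seeds 1–10,
sizes at which the full pipeline runs in seconds per seed. The interval
Jaccard used for recovery scoring is intersection-over-union of called
versus planted base pairs (both-empty defined as 1). Degenerate inputs:
empty tracks, empty variant lists and empty clusters are legal and produce
empty outputs; all-zero coverage has no diploid peak and raises.

## Known limitations

* The diploid-peak estimator assumes a unimodal depth distribution; heavy
  duplication or contamination (extra modes) can mislead it, which is why
  the CLI accepts explicit `--female-peak/--male-peak` overrides.
* Thresholds are deterministic filters, not statistical tests; no
  significance is attached to a called region.
* The contig classifier consumes precomputed coverage summaries; depth
  computation from alignments (e.g. `bedtools genomecov`) is upstream and
  out of scope, as is variant calling itself.
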