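# poolsex

Discovery of sex-specific genomic regions from pooled whole-genome
sequencing of the two sexes, for species with homomorphic (undifferentiated)
sex chromosomes — the situation in sturgeons and many other poikilothermic
vertebrates, where the W-specific sequence can be a few kilobases on an
otherwise recombining chromosome and is invisible to karyotyping.

The package is aimed at researchers who have one sequencing pool per
phenotypic sex mapped to a reference assembly and want to locate the
sex-limited haplotype, without per-individual genotyping. It implements
three complementary analyses plus the downstream marker validation:

1. **Differential coverage.** Per-pool per-bp depth tracks are normalized so
   that 1.0 equals the diploid coverage peak (the mode of the bp-mass depth
   histogram; a W-specific region then sits near 0.5 in the female pool and
   near 0 in the male pool). Candidate regions are maximal runs of base
   pairs with

   `depth_opposite <= c_max` (default 0) **and** `depth_target > c_min` (default 0.3),

   merged when closer than `d` bp (default 30, `bedtools merge -d`
   semantics) and kept when at least `L` bp long (default 160). A
   swapped-sex control repeats the call with the pool roles exchanged;
   a genuine signal appears in one direction only.
2. **Sex-specific variants.** Pooled variant calls (VCF with per-sample
   allele depths, or a plain allele-count table) are screened for sites
   with ≥ 10 alternate-allele reads in the target-sex pool and ≤ 0 in the
   other, then chained into clusters whenever successive variants are
   within 4000 bp; clusters are ranked by variant count.
3. **Contig classification.** Contigs assembled from unmapped reads and
   remapped are labelled female-/male-specific when their normalized mean
   coverage is haploid (0.3–0.7) in one pool and spurious (≤ 0.1) in the
   other.
4. **Marker–sex concordance.** Presence/absence of a candidate PCR marker
   against phenotypic sex per species is tested with Pearson's χ² with
   Yates' continuity correction,
   `χ² = N (|ad − bc| − N/2)₊² / (R₁R₂C₁C₂)`, p from χ²₁.

A synthetic ZW scenario generator produces all of the above inputs with
planted ground truth (a 16 kb W insertion, 42×/37× coverage peaks, short
mismapping artifacts, 27 W-linked variants, fully concordant genotype
tables), so the entire pipeline is testable at desk scale.

## Worked example

A full synthetic run — simulate, normalize, call regions with the swapped
control, screen and cluster variants, classify contigs, test concordance:

```
$ poolsex run --seed 1 --outdir demo_run
5 candidate regions (15131 bp), 0 control regions, 19 screened variants,
6 species tested -> demo_run/summary.json
```

`demo_run/summary.json` then contains (abridged):

```json
{
  "female_diploid_peak": 41.0,
  "male_diploid_peak": 37.0,
  "n_candidate_regions": 5,
  "candidate_region_bp": 15131,
  "n_control_regions": 0,
  "n_variants_screened": 19,
  "top_cluster": {"chrom": "ZW_scaffold_1", "start": 616106, "end": 631803, "n_variants": 19},
  "cluster_region_same_chrom": true,
  "cluster_region_distance_bp": 106651,
  "region_truth_jaccard": 0.9457,
  "top_cluster_overlaps_truth": true
}
```

Reading: both pools' diploid peaks are recovered from the depth histograms
(a Poisson depth with integer mean has tied modes at mean−1 and mean; ties
resolve downward). The planted 16 kb W insertion is recovered as 5 merged
blocks totalling 15.1 kb (Jaccard 0.95 against truth — mismapping runs in
the male pool punch short holes), the swapped-sex control is empty, 19 of
the 27 planted W-linked variants survive the (10, 0) read screen and form
the top-ranked cluster, which lies on the same chromosome as the called
region at a known planted distance. The six genotype designs reproduce
p-values down to 5.4 × 10⁻¹³ in `demo_run/association.tsv`.

Individual steps are available as subcommands (`poolsex simulate`,
`poolsex regions`, `poolsex variants screen|cluster`,
`poolsex classify-contigs`, `poolsex assoc`) and as library functions; real
bedgraph/VCF/TSV inputs are accepted through the same interfaces (see
`RunConfig.inputs`).

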