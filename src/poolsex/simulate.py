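"""Synthetic ZW pool-seq scenarios with planted ground truth.

The generator emulates the data a two-pool (female/male) resequencing study
of a ZZ/ZW species produces after mapping, at the level the analysis
consumes — per-bp depth tracks, pooled allele counts, contig coverage
summaries and per-individual marker tables — without simulating reads:

* a Z-backbone "male assembly" and a "female assembly" that carries an
  additional W-specific insertion (default 16 kb);
* per-bp Poisson depth around each pool's diploid peak (defaults 42x
  female, 37x male), haploid depth (peak/2) for the female pool across the
  W insertion, and zero male-pool depth there except short mismapping runs
  (geometric lengths, capped) planted at a per-bp rate;
* W-linked variant sites whose alternate allele rides on the W haplotype
  (female-pool alt reads ~ Binomial(depth, 1/4); male-pool alt reads 0),
  clustered in a window on the same chromosome at a configurable distance
  from the insertion, on a background of shared polymorphisms with matched
  pool frequencies;
* contig coverage summaries mixing W-private (haploid/spurious) and
  autosomal (diploid/diploid) patterns;
* per-species marker-by-sex tables with perfect concordance by default.

All randomness flows from a single integer seed; identical seeds give
identical outputs, file for file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from poolsex import io as psio
from poolsex.contigs import ContigCoverageSummary
from poolsex.io import CoverageTrack
from poolsex.variants import PooledVariantSite

__all__ = [
    "ScenarioParams",
    "SimTruth",
    "SimGenomes",
    "PoolTracks",
    "ScenarioResult",
    "TABLE1_DESIGNS",
    "simulate_genomes",
    "simulate_pool_tracks",
    "simulate_variant_table",
    "simulate_genotypes",
    "simulate_contig_summaries",
    "simulate_scenario",
]

FEMALE_CHROM = "ZW_scaffold_1"
MALE_CHROM = "Z_scaffold_1"

#: published marker-validation designs: species -> (marker-positive females
#: out of n females, n males all marker-negative)
TABLE1_DESIGNS: dict[str, tuple[int, int]] = {
    "A. sturio": (18, 18),
    "A. oxyrinchus": (12, 15),
    "H. huso": (12, 16),
    "A. ruthenus": (25, 27),
    "A. baerii": (28, 28),
    "A. gueldenstaedtii": (15, 12),
}

# distinct sub-streams so each fixture kind is independent under one seed
_TAG_GENOME, _TAG_TRACKS, _TAG_VARIANTS, _TAG_GENOTYPES, _TAG_CONTIGS = range(5)


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), tag])


@dataclass
class ScenarioParams:
    """Study conditions of the synthetic ZW scenario.

    Defaults mirror the sterlet-style pool-seq design the analysis targets:
    a 1 Mb Z backbone with a 16 kb W-specific insertion, diploid coverage
    peaks of 42x (female pool) and 37x (male pool), a per-bp mismapping
    rate of 5e-4 producing sub-200 bp spurious runs, 27 W-linked variant
    sites clustered in a 16 kb window downstream of the insertion, and the
    six published marker-validation designs.
    """

    genome_length: int = 1_000_000
    w_region_start: int = 500_000
    w_region_length: int = 16_000
    n_w_linked_snps: int = 27
    snp_window_length: int = 16_000
    snp_window_offset: int = 100_000  # gap between W region end and SNP window
    w_allele_fraction: float = 0.25   # one W among the four pool haplotypes
    n_background_snps: int = 1000
    female_peak: float = 42.0
    male_peak: float = 37.0
    mismap_rate: float = 5e-4
    spurious_match_mean_len: int = 80
    spurious_match_max_len: int = 200
    spurious_depth_mean: float = 2.0
    n_female_specific_contigs: int = 1067
    n_autosomal_contigs: int = 500
    n_male_specific_contigs: int = 0
    contig_len_mean: int = 617
    contig_len_min: int = 150
    contig_spurious_cov: float = 0.02
    genotype_designs: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(TABLE1_DESIGNS)
    )
    genotyping_error: float = 0.0

    def __post_init__(self) -> None:
        if self.w_region_length < 0:
            raise ValueError("w_region_length must be >= 0")
        if not 0 <= self.w_region_start <= self.genome_length:
            raise ValueError("w_region_start outside the genome")
        if not 0 <= self.mismap_rate < 1:
            raise ValueError("mismap_rate must be in [0, 1)")
        if self.female_peak <= 0 or self.male_peak <= 0:
            raise ValueError("coverage peaks must be > 0")
        end = self.snp_window_start + self.snp_window_length
        if self.n_w_linked_snps > 0 and end > self.female_assembly_length:
            raise ValueError("SNP window exceeds the female assembly")

    @property
    def w_region_end(self) -> int:
        return self.w_region_start + self.w_region_length

    @property
    def female_assembly_length(self) -> int:
        return self.genome_length + self.w_region_length

    @property
    def snp_window_start(self) -> int:
        return self.w_region_end + self.snp_window_offset


@dataclass
class SimTruth:
    """Planted ground truth, consistent with the emitted fixtures."""

    w_interval: tuple[str, int, int]
    snp_window: tuple[str, int, int]
    snp_positions: list[int]
    genotype_designs: dict[str, tuple[int, int]]


@dataclass
class SimGenomes:
    male_assembly: dict[str, str]
    female_assembly: dict[str, str]
    truth_interval: tuple[str, int, int]


@dataclass
class PoolTracks:
    """The four depth tracks: each pool mapped to each assembly."""

    female_on_female: dict[str, CoverageTrack]
    male_on_female: dict[str, CoverageTrack]
    female_on_male: dict[str, CoverageTrack]
    male_on_male: dict[str, CoverageTrack]


@dataclass
class ScenarioResult:
    params: ScenarioParams
    seed: int
    truth: SimTruth
    tracks: PoolTracks
    variants: list[PooledVariantSite]
    genotypes: pd.DataFrame
    contig_summaries: list[ContigCoverageSummary]
    genomes: SimGenomes | None = None


def simulate_genomes(params: ScenarioParams, seed: int) -> SimGenomes:
    """Random Z backbone plus a female assembly with the W insertion.

    The female assembly equals the male (Z) assembly with a W-specific
    random sequence inserted at ``w_region_start``; with
    ``w_region_length=0`` the two assemblies are identical and the truth
    interval is empty.
    """
    rng = _rng(seed, _TAG_GENOME)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    z = rng.choice(bases, size=params.genome_length)
    w = rng.choice(bases, size=params.w_region_length)
    s = params.w_region_start
    female = np.concatenate([z[:s], w, z[s:]])
    return SimGenomes(
        male_assembly={MALE_CHROM: z.tobytes().decode()},
        female_assembly={FEMALE_CHROM: female.tobytes().decode()},
        truth_interval=(FEMALE_CHROM, s, s + params.w_region_length),
    )


def simulate_pool_tracks(params: ScenarioParams, seed: int) -> PoolTracks:
    """Per-bp Poisson depth tracks for both pools on both assemblies.

    On the female assembly the female pool drops to haploid depth (peak/2)
    across the W insertion while the male pool is zero there apart from
    mismapping runs: run starts are planted per-bp at ``mismap_rate``, run
    lengths are geometric with mean ``spurious_match_mean_len`` capped at
    ``spurious_match_max_len``, and run depth is 1 + Poisson(spurious mean).
    The male assembly carries no sex-specific signal (both pools diploid).
    """
    rng = _rng(seed, _TAG_TRACKS)
    ws, we = params.w_region_start, params.w_region_end
    w = params.w_region_length
    lf, lm = params.female_assembly_length, params.genome_length

    fem_f = rng.poisson(params.female_peak, lf).astype(float)
    fem_f[ws:we] = rng.poisson(params.female_peak / 2.0, w)
    male_f = rng.poisson(params.male_peak, lf).astype(float)
    male_f[ws:we] = 0.0
    if w and params.mismap_rate > 0:
        starts = ws + np.flatnonzero(rng.random(w) < params.mismap_rate)
        for s in starts:
            run = min(
                int(rng.geometric(1.0 / params.spurious_match_mean_len)),
                params.spurious_match_max_len,
            )
            depth = 1 + rng.poisson(params.spurious_depth_mean)
            male_f[s : min(s + run, we)] = depth

    fem_m = rng.poisson(params.female_peak, lm).astype(float)
    male_m = rng.poisson(params.male_peak, lm).astype(float)

    return PoolTracks(
        female_on_female={FEMALE_CHROM: CoverageTrack.from_dense(FEMALE_CHROM, fem_f)},
        male_on_female={FEMALE_CHROM: CoverageTrack.from_dense(FEMALE_CHROM, male_f)},
        female_on_male={MALE_CHROM: CoverageTrack.from_dense(MALE_CHROM, fem_m)},
        male_on_male={MALE_CHROM: CoverageTrack.from_dense(MALE_CHROM, male_m)},
    )


def simulate_variant_table(
    params: ScenarioParams, seed: int
) -> tuple[list[PooledVariantSite], SimTruth]:
    """Pooled allele-count table with planted W-linked variants.

    W-linked sites: female-pool alt reads ~ Binomial(depth, w_allele_fraction)
    at diploid depth, male-pool alt reads 0 — the pattern of an allele
    private to the W haplotype in shared sequence. Background sites carry a
    shared allele frequency drawn once per site and applied to both pools.
    Sites are returned sorted by position; the truth records the planted
    window and positions.
    """
    rng = _rng(seed, _TAG_VARIANTS)
    alleles = np.array(list("ACGT"))
    sites: list[tuple[int, bool]] = []

    win_s = params.snp_window_start
    win_e = win_s + params.snp_window_length
    n_w = params.n_w_linked_snps
    w_pos: np.ndarray = np.array([], dtype=int)
    if n_w > 0:
        w_pos = np.sort(rng.choice(np.arange(win_s, win_e), size=n_w, replace=False))
    bg_pos = np.sort(
        rng.choice(params.female_assembly_length, size=params.n_background_snps,
                   replace=False)
    )
    bg_pos = bg_pos[~np.isin(bg_pos, w_pos)]

    out: list[PooledVariantSite] = []
    for pos, linked in sorted(
        [(int(p), True) for p in w_pos] + [(int(p), False) for p in bg_pos]
    ):
        ref, alt = rng.choice(alleles, size=2, replace=False)
        fem_depth = int(rng.poisson(params.female_peak))
        male_depth = int(rng.poisson(params.male_peak))
        if linked:
            fem_alt = int(rng.binomial(fem_depth, params.w_allele_fraction))
            male_alt = 0
        else:
            freq = rng.uniform(0.05, 0.95)
            fem_alt = int(rng.binomial(fem_depth, freq))
            male_alt = int(rng.binomial(male_depth, freq))
        out.append(
            PooledVariantSite(
                chrom=FEMALE_CHROM, pos=pos, ref=str(ref), alt=str(alt),
                fem_ref=fem_depth - fem_alt, fem_alt=fem_alt,
                male_ref=male_depth - male_alt, male_alt=male_alt,
            )
        )
    truth = SimTruth(
        w_interval=(FEMALE_CHROM, params.w_region_start, params.w_region_end),
        snp_window=(FEMALE_CHROM, win_s, win_e),
        snp_positions=[int(p) for p in w_pos],
        genotype_designs=dict(params.genotype_designs),
    )
    return out, truth


def simulate_genotypes(params: ScenarioParams, seed: int) -> pd.DataFrame:
    """Per-individual marker-by-sex table for each design.

    With ``genotyping_error=0`` every female is marker-positive and every
    male marker-negative (perfect concordance); a positive error rate flips
    calls independently.
    """
    rng = _rng(seed, _TAG_GENOTYPES)
    rows = []
    for species, (n_f, n_m) in params.genotype_designs.items():
        tag = species.replace(" ", "_").replace(".", "")
        for sex, n in (("female", n_f), ("male", n_m)):
            for i in range(n):
                call = "positive" if sex == "female" else "negative"
                if params.genotyping_error and rng.random() < params.genotyping_error:
                    call = "negative" if call == "positive" else "positive"
                rows.append((f"{tag}_{sex[0]}{i + 1}", species, sex, call))
    return pd.DataFrame(rows, columns=psio.GENOTYPE_COLUMNS)


def simulate_contig_summaries(
    params: ScenarioParams, seed: int
) -> list[ContigCoverageSummary]:
    """Coverage summaries for a mix of W-private and autosomal contigs.

    W-private contigs get haploid female coverage (read mass ~
    Poisson(0.5 * peak * len)) and only spurious male coverage; autosomal
    contigs are diploid in both pools. Lengths are geometric above a floor.
    """
    rng = _rng(seed, _TAG_CONTIGS)
    mean_extra = max(params.contig_len_mean - params.contig_len_min, 1)

    def lengths(n: int) -> np.ndarray:
        return params.contig_len_min + rng.geometric(1.0 / mean_extra, size=n) - 1

    def mean_cov(n_bp: np.ndarray, copies: float, peak: float) -> np.ndarray:
        # length-weighted mean of per-bp Poisson depth, normalized by peak
        return rng.poisson(copies / 2.0 * peak * n_bp) / (n_bp * peak)

    out: list[ContigCoverageSummary] = []
    specs = [
        ("wcontig", params.n_female_specific_contigs, 1.0, "spur"),
        ("mcontig", params.n_male_specific_contigs, "spur", 1.0),
        ("acontig", params.n_autosomal_contigs, 2.0, 2.0),
    ]
    for prefix, n, fem_copies, male_copies in specs:
        if n == 0:
            continue
        ln = lengths(n)
        if fem_copies == "spur":
            fem = rng.poisson(params.contig_spurious_cov * params.female_peak * ln) / (
                ln * params.female_peak
            )
        else:
            fem = mean_cov(ln, float(fem_copies), params.female_peak)
        if male_copies == "spur":
            male = rng.poisson(params.contig_spurious_cov * params.male_peak * ln) / (
                ln * params.male_peak
            )
        else:
            male = mean_cov(ln, float(male_copies), params.male_peak)
        out.extend(
            ContigCoverageSummary(f"{prefix}_{i + 1}", int(l), float(f), float(m))
            for i, (l, f, m) in enumerate(zip(ln, fem, male))
        )
    return out


def simulate_scenario(
    params: ScenarioParams | None = None,
    seed: int = 1,
    outdir: str | Path | None = None,
    include_genomes: bool = False,
) -> ScenarioResult:
    """Generate every fixture of one scenario; optionally write them out.

    When ``outdir`` is given, emits the assemblies (FASTA), the four depth
    tracks (BEDGRAPH), the variant table (TSV and VCF), the genotype table
    (TSV), contig summaries (TSV), the planted truth (BED) and a JSON
    manifest of the parameters. ``include_genomes`` forces sequence
    simulation even without an output directory.
    """
    params = params or ScenarioParams()
    tracks = simulate_pool_tracks(params, seed)
    variants, truth = simulate_variant_table(params, seed)
    genotypes = simulate_genotypes(params, seed)
    contig_summaries = simulate_contig_summaries(params, seed)
    genomes = (
        simulate_genomes(params, seed) if (include_genomes or outdir) else None
    )
    result = ScenarioResult(
        params=params, seed=int(seed), truth=truth, tracks=tracks,
        variants=variants, genotypes=genotypes,
        contig_summaries=contig_summaries, genomes=genomes,
    )
    if outdir is not None:
        _write_scenario(result, Path(outdir))
    return result


def _write_scenario(result: ScenarioResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    assert result.genomes is not None
    psio.write_fasta(result.genomes.male_assembly, outdir / "male_assembly.fasta")
    psio.write_fasta(result.genomes.female_assembly, outdir / "female_assembly.fasta")
    t = result.tracks
    psio.write_bedgraph(t.female_on_female, outdir / "female_pool.female_assembly.bedgraph")
    psio.write_bedgraph(t.male_on_female, outdir / "male_pool.female_assembly.bedgraph")
    psio.write_bedgraph(t.female_on_male, outdir / "female_pool.male_assembly.bedgraph")
    psio.write_bedgraph(t.male_on_male, outdir / "male_pool.male_assembly.bedgraph")
    psio.write_variant_table(result.variants, outdir / "variants.tsv")
    psio.write_pool_vcf(
        result.variants, outdir / "variants.vcf",
        contigs={FEMALE_CHROM: result.params.female_assembly_length},
    )
    psio.write_genotype_table(result.genotypes, outdir / "genotypes.tsv")
    pd.DataFrame(
        [(c.contig, c.length, c.fem_cov, c.male_cov) for c in result.contig_summaries],
        columns=["contig", "length", "fem_cov", "male_cov"],
    ).to_csv(outdir / "contig_summaries.tsv", sep="\t", index=False)
    with open(outdir / "truth.bed", "w") as fh:
        c, s, e = result.truth.w_interval
        if e > s:
            fh.write(f"{c}\t{s}\t{e}\tW_region\n")
        c, s, e = result.truth.snp_window
        if result.truth.snp_positions:
            fh.write(f"{c}\t{s}\t{e}\tW_snp_window\n")
    manifest = {
        "seed": result.seed,
        "params": dataclasses.asdict(result.params),
        "truth": dataclasses.asdict(result.truth),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
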