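"""End-to-end orchestration: simulate/load -> normalize -> regions ->
variants -> contigs -> association, with a machine-readable summary.

A run either generates a synthetic scenario (the default) or consumes real
inputs (bedgraphs, a variant table or VCF, genotype and contig-summary
TSVs) named in the config. Every output lands in the run directory together
with a manifest capturing parameters, seed and package version, so a run is
reproducible from its own artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

import poolsex
from poolsex import io as psio
from poolsex.association import association_report
from poolsex.contigs import (
    ContigClassParams,
    classify_contigs,
    read_contig_summaries,
    write_classified_contigs,
)
from poolsex.coverage import (
    RegionCallParams,
    estimate_diploid_peak,
    interval_jaccard,
    normalize_tracks,
    swapped_control,
)
from poolsex.simulate import ScenarioParams, simulate_scenario
from poolsex.variants import ScreenParams, cluster_variants, screen_variants

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips to the manifest."""

    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    region_params: RegionCallParams = field(default_factory=RegionCallParams)
    screen_params: ScreenParams = field(default_factory=ScreenParams)
    contig_params: ContigClassParams = field(default_factory=ContigClassParams)
    cluster_max_gap: int = 4000
    target_sex: str = "female"
    seed: int = 1
    outdir: str = "poolsex_run"
    write_fixtures: bool = True
    #: real-data mode: paths for female_bedgraph, male_bedgraph, variants
    #: (TSV) or vcf + female_sample/male_sample, genotypes, contig_summaries
    inputs: dict[str, str] | None = None

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        for name, sub_cls in (
            ("scenario", ScenarioParams),
            ("region_params", RegionCallParams),
            ("screen_params", ScreenParams),
            ("contig_params", ContigClassParams),
        ):
            if name in raw:
                block = raw.pop(name)
                if name == "scenario" and "genotype_designs" in block:
                    block["genotype_designs"] = {
                        k: tuple(v) for k, v in block["genotype_designs"].items()
                    }
                kwargs[name] = sub_cls(**block)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the machine-readable summary.

    Outputs written under ``config.outdir``: candidate and control region
    BEDs, screened-variant and cluster TSVs, classified-contig TSV,
    per-species association TSV, ``summary.json`` and ``manifest.json``
    (plus the simulated fixtures when in synthetic mode).
    """
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    steps: dict[str, float] = {}

    def tick(name: str) -> None:
        steps[name] = round(time.perf_counter() - t0 - sum(steps.values()), 3)
        logger.info("step %-22s %6.2f s", name, steps[name])

    # ------------------------------------------------------------------ data
    truth = None
    if config.inputs is None:
        fixture_dir = outdir / "simulated" if config.write_fixtures else None
        scen = simulate_scenario(config.scenario, seed=config.seed, outdir=fixture_dir)
        truth = scen.truth
        fem_tracks, male_tracks = scen.tracks.female_on_female, scen.tracks.male_on_female
        variants = scen.variants
        genotypes = scen.genotypes
        contig_summaries = scen.contig_summaries
    else:
        inp = dict(config.inputs)
        missing = {"female_bedgraph", "male_bedgraph"} - set(inp)
        if missing:
            raise FileNotFoundError(f"config.inputs missing {sorted(missing)}")
        for key in ("female_bedgraph", "male_bedgraph", "variants", "vcf",
                    "genotypes", "contig_summaries"):
            if key in inp and not Path(inp[key]).exists():
                raise FileNotFoundError(f"input {key!r}: no such file {inp[key]}")
        fem_tracks = psio.read_bedgraph(inp["female_bedgraph"])
        male_tracks = psio.read_bedgraph(inp["male_bedgraph"])
        if "vcf" in inp:
            variants = psio.read_pool_vcf(
                inp["vcf"], inp.get("female_sample", "female_pool"),
                inp.get("male_sample", "male_pool"),
            )
        elif "variants" in inp:
            variants = psio.read_variant_table(inp["variants"])
        else:
            variants = []
        genotypes = (
            psio.read_genotype_table(inp["genotypes"]) if "genotypes" in inp else None
        )
        contig_summaries = (
            read_contig_summaries(inp["contig_summaries"])
            if "contig_summaries" in inp
            else []
        )
    tick("load_or_simulate")

    # ------------------------------------------------- coverage differential
    fem_peak = estimate_diploid_peak(fem_tracks)
    male_peak = estimate_diploid_peak(male_tracks)
    fem_norm = normalize_tracks(fem_tracks, peak=fem_peak)
    male_norm = normalize_tracks(male_tracks, peak=male_peak)
    report = swapped_control(
        fem_norm, male_norm, config.region_params, target_sex=config.target_sex
    )
    psio.write_bed(report.target_regions, outdir / "candidate_regions.bed")
    psio.write_bed(report.control_regions, outdir / "control_regions.bed")
    tick("regions")

    # --------------------------------------------------------------- variants
    screened = screen_variants(variants, config.screen_params)
    clusters = cluster_variants(screened, max_gap=config.cluster_max_gap)
    psio.write_variant_table(screened, outdir / "screened_variants.tsv")
    pd.DataFrame(
        [(c.chrom, c.start, c.end, c.count) for c in clusters],
        columns=["chrom", "start", "end", "n_variants"],
    ).to_csv(outdir / "variant_clusters.tsv", sep="\t", index=False)
    tick("variants")

    # ---------------------------------------------------------------- contigs
    classified, totals = classify_contigs(contig_summaries, config.contig_params)
    write_classified_contigs(classified, outdir / "classified_contigs.tsv")
    tick("contigs")

    # ------------------------------------------------------------ association
    if genotypes is not None and len(genotypes):
        assoc = association_report(genotypes)
        assoc.to_csv(outdir / "association.tsv", sep="\t", index=False)
    else:
        assoc = pd.DataFrame()
    tick("association")

    # ----------------------------------------------------------------- summary
    summary: dict[str, Any] = {
        "female_diploid_peak": fem_peak,
        "male_diploid_peak": male_peak,
        "n_candidate_regions": report.n_target,
        "candidate_region_bp": report.target_bp,
        "n_control_regions": report.n_control,
        "control_region_bp": report.control_bp,
        "n_variants_input": len(variants),
        "n_variants_screened": len(screened),
        "n_variant_clusters": len(clusters),
        "contig_totals": {
            lab: {"count": t.count, "total_bp": t.total_bp}
            for lab, t in totals.items()
        },
        "n_species_tested": int(len(assoc)),
    }
    if clusters and report.target_regions:
        top = clusters[0]
        region = max(report.target_regions, key=lambda r: r.length)
        same = top.chrom == region.chrom
        distance = None
        if same:
            distance = max(0, max(region.start - top.end, top.start - region.end))
        summary["top_cluster"] = {
            "chrom": top.chrom, "start": top.start, "end": top.end,
            "n_variants": top.count,
        }
        summary["top_region"] = {
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "length": region.length,
        }
        summary["cluster_region_same_chrom"] = same
        summary["cluster_region_distance_bp"] = distance
    if truth is not None:
        called = [(r.chrom, r.start, r.end) for r in report.target_regions]
        w_c, w_s, w_e = truth.w_interval
        truth_ivs = [(w_c, w_s, w_e)] if w_e > w_s else []
        summary["region_truth_jaccard"] = round(interval_jaccard(called, truth_ivs), 4)
        if clusters and truth.snp_positions:
            top = clusters[0]
            t_c, t_s, t_e = truth.snp_window
            summary["top_cluster_overlaps_truth"] = bool(
                top.chrom == t_c and top.start <= t_e and top.end >= t_s
            )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")

    manifest = {
        "package": "poolsex",
        "version": poolsex.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    logger.info("run complete in %.2f s -> %s", time.perf_counter() - t0, outdir)
    return summary
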