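"""Classify assembled contigs as sex-specific from per-pool coverages.

Contigs assembled from reads that did not map to a reference can be added
back to it and the pools remapped; a contig private to the W haplotype then
shows roughly haploid normalized coverage (~0.5) in the female pool and only
spurious coverage in the male pool. The classifier is a band predicate on
the two length-weighted mean normalized coverages, symmetric in sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "ContigCoverageSummary",
    "ContigClassParams",
    "ClassifiedContig",
    "LabelTotals",
    "classify_contigs",
    "read_contig_summaries",
    "write_classified_contigs",
]

LABELS = ("female-specific", "male-specific", "unassigned")


@dataclass(frozen=True)
class ContigCoverageSummary:
    """Length-weighted mean normalized coverage of one contig per pool."""

    contig: str
    length: int
    fem_cov: float
    male_cov: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.contig}: length must be > 0")
        if self.fem_cov < 0 or self.male_cov < 0:
            raise ValueError(f"{self.contig}: negative coverage")


@dataclass(frozen=True)
class ContigClassParams:
    """Coverage bands defining "haploid in one sex, spurious in the other".

    ``haploid_low``..``haploid_high`` (default 0.3–0.7) brackets the
    theoretical haploid expectation of 0.5 with sampling slack;
    ``max_spurious`` (default 0.1) is the ceiling tolerated in the
    opposite-sex pool.
    """

    haploid_low: float = 0.3
    haploid_high: float = 0.7
    max_spurious: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.haploid_low < self.haploid_high:
            raise ValueError("need 0 < haploid_low < haploid_high")
        if self.max_spurious >= self.haploid_low:
            raise ValueError("max_spurious must be < haploid_low")


@dataclass(frozen=True)
class ClassifiedContig:
    summary: ContigCoverageSummary
    label: str


@dataclass(frozen=True)
class LabelTotals:
    count: int
    total_bp: int


def classify_contigs(
    summaries: Sequence[ContigCoverageSummary],
    params: ContigClassParams | None = None,
) -> tuple[list[ClassifiedContig], dict[str, LabelTotals]]:
    """Label each contig and tally per-label counts and summed bp.

    female-specific: female coverage within the haploid band and male
    coverage <= max_spurious; male-specific is the mirror image; everything
    else (autosomal diploid patterns included) is unassigned. Labels are
    mutually exclusive and exhaustive (``max_spurious < haploid_low``
    guarantees the two specific bands cannot both fire).
    """
    params = params or ContigClassParams()
    classified = [ClassifiedContig(s, _label(s, params)) for s in summaries]
    totals = {
        lab: LabelTotals(
            count=sum(1 for c in classified if c.label == lab),
            total_bp=sum(c.summary.length for c in classified if c.label == lab),
        )
        for lab in LABELS
    }
    return classified, totals


def _label(s: ContigCoverageSummary, p: ContigClassParams) -> str:
    if p.haploid_low <= s.fem_cov <= p.haploid_high and s.male_cov <= p.max_spurious:
        return "female-specific"
    if p.haploid_low <= s.male_cov <= p.haploid_high and s.fem_cov <= p.max_spurious:
        return "male-specific"
    return "unassigned"


def read_contig_summaries(path: str | Path) -> list[ContigCoverageSummary]:
    """Read a TSV with columns contig, length, fem_cov, male_cov."""
    df = pd.read_csv(path, sep="\t")
    missing = {"contig", "length", "fem_cov", "male_cov"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ContigCoverageSummary(
            contig=str(r.contig), length=int(r.length),
            fem_cov=float(r.fem_cov), male_cov=float(r.male_cov),
        )
        for r in df.itertuples(index=False)
    ]


def write_classified_contigs(
    classified: Sequence[ClassifiedContig], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (c.summary.contig, c.summary.length, c.summary.fem_cov,
             c.summary.male_cov, c.label)
            for c in classified
        ],
        columns=["contig", "length", "fem_cov", "male_cov", "label"],
    ).to_csv(path, sep="\t", index=False)
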