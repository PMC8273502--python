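"""Sex-specific variant screening and distance clustering of pooled calls.

A variant is *sex-specific* when the alternate allele is well supported by
reads in one sex pool and (almost) unsupported in the other. The read-count
cutoffs act on alternate-allele-supporting reads, not on site depth: a locus
absent from one sex still accumulates reference-allele coverage there, so
total depth cannot separate the sexes.

Screened variants are then chained into clusters by genomic distance
(single linkage, default maximum inter-variant gap 4000 bp) and the clusters
are ranked by how many variants they contain — the field's usual way of
prioritising candidate sex-determining loci for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PooledVariantSite",
    "ScreenParams",
    "VariantCluster",
    "screen_variants",
    "cluster_variants",
]

SEXES = ("female", "male")


@dataclass(frozen=True)
class PooledVariantSite:
    """A biallelic variant with per-pool supporting read counts.

    Positions are 0-based. ``ref``/``alt`` are allele strings, so SNPs, MNPs
    and INDELs are all representable (length-variant strings).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    fem_ref: int
    fem_alt: int
    male_ref: int
    male_alt: int

    def __post_init__(self) -> None:
        if min(self.fem_ref, self.fem_alt, self.male_ref, self.male_alt) < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")
        if not self.alt:
            raise ValueError(f"empty alt allele at {self.chrom}:{self.pos}")

    def alt_reads(self, sex: str) -> int:
        """Alternate-allele-supporting reads in the given sex pool."""
        if sex == "female":
            return self.fem_alt
        if sex == "male":
            return self.male_alt
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")


@dataclass(frozen=True)
class ScreenParams:
    """Read-count cutoffs for the sex-specificity screen.

    ``min_target_reads`` is the floor on alt reads in the target-sex pool,
    ``max_opposite_reads`` the ceiling on alt reads in the other pool.
    Defaults (10, 0) are the strictest end of the cutoff grids typically
    explored for pool-seq sex screens.
    """

    target_sex: str = "female"
    max_opposite_reads: int = 0
    min_target_reads: int = 10

    def __post_init__(self) -> None:
        if self.target_sex not in SEXES:
            raise ValueError(f"target_sex must be one of {SEXES}")
        if self.max_opposite_reads < 0:
            raise ValueError("max_opposite_reads must be >= 0")
        if self.min_target_reads < 1:
            raise ValueError("min_target_reads must be >= 1")

    @property
    def opposite_sex(self) -> str:
        return "male" if self.target_sex == "female" else "female"


@dataclass
class VariantCluster:
    """A run of screened variants whose successive positions are within
    ``max_gap`` of each other; ``start``/``end`` span the member positions."""

    chrom: str
    start: int
    end: int
    count: int
    members: list[PooledVariantSite] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("cluster end < start")
        if self.count < 1:
            raise ValueError("cluster must contain at least one variant")


def screen_variants(
    sites: list[PooledVariantSite], params: ScreenParams | None = None
) -> list[PooledVariantSite]:
    """Retain sites sex-specific under the read-count cutoffs.

    A site passes when its alt-supporting reads are >= ``min_target_reads``
    in the target-sex pool and <= ``max_opposite_reads`` in the opposite
    pool. Input order is preserved; the result may be empty.
    """
    params = params or ScreenParams()
    tgt, opp = params.target_sex, params.opposite_sex
    return [
        s
        for s in sites
        if s.alt_reads(tgt) >= params.min_target_reads
        and s.alt_reads(opp) <= params.max_opposite_reads
    ]


def cluster_variants(
    sites: list[PooledVariantSite], max_gap: int = 4000
) -> list[VariantCluster]:
    """Chain variants into clusters by genomic distance, per chromosome.

    Single-linkage chaining: walking the (chrom, pos)-sorted input, a new
    cluster opens whenever the distance to the previous variant exceeds
    ``max_gap`` (distance measured between successive start positions;
    INDEL span is ignored). Clusters are returned sorted by member count
    descending, ties broken by genomic order.

    Raises ``ValueError`` if the input is not sorted by (chrom, pos).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    keys = [(s.chrom, s.pos) for s in sites]
    if keys != sorted(keys):
        raise ValueError("sites must be sorted by (chrom, pos)")

    clusters: list[VariantCluster] = []
    current: list[PooledVariantSite] = []
    for site in sites:
        if current and (
            site.chrom != current[-1].chrom or site.pos - current[-1].pos > max_gap
        ):
            clusters.append(_close(current))
            current = []
        current.append(site)
    if current:
        clusters.append(_close(current))

    clusters.sort(key=lambda c: (-c.count, c.chrom, c.start))
    return clusters


def _close(members: list[PooledVariantSite]) -> VariantCluster:
    return VariantCluster(
        chrom=members[0].chrom,
        start=members[0].pos,
        end=members[-1].pos,
        count=len(members),
        members=list(members),
    )
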