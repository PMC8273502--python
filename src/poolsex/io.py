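"""Readers/writers for the on-disk formats the pipeline touches.

All internal coordinates are 0-based half-open (the BED/BEDGRAPH
convention). VCF is ingested as 1-based and shifted on read. Zero-coverage
gaps are implicit in BEDGRAPH files but treated as depth 0 wherever two
tracks are combined or filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from poolsex.variants import PooledVariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "UnionTrack",
    "BedgraphFormatError",
    "read_bedgraph",
    "write_bedgraph",
    "union_coverage",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_pool_vcf",
    "write_pool_vcf",
    "read_variant_table",
    "write_variant_table",
    "read_genotype_table",
    "write_genotype_table",
]

GENOTYPE_COLUMNS = ["individual", "species", "sex", "marker"]
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "fem_ref", "fem_alt", "male_ref", "male_alt",
]


class BedgraphFormatError(ValueError):
    """Malformed BEDGRAPH input; the message names the offending line."""


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping depth intervals on one chromosome.

    ``starts``/``ends`` are 0-based half-open; ``values`` are read depths
    (raw) or diploid units (normalized, in which case ``peak`` records the
    diploid coverage peak the track was divided by).
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    peak: float | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts/ends/values length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError(f"{self.chrom}: interval with end <= start")
        if np.any(self.values < 0):
            raise ValueError(f"{self.chrom}: negative coverage value")
        if len(self.starts) > 1:
            if np.any(np.diff(self.starts) < 0):
                raise ValueError(f"{self.chrom}: intervals not sorted by start")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValueError(f"{self.chrom}: overlapping intervals")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def is_normalized(self) -> bool:
        return self.peak is not None

    @property
    def span(self) -> int:
        """End of the last interval (0 for an empty track)."""
        return int(self.ends[-1]) if len(self) else 0

    def total_mass(self) -> float:
        """Sum over covered bp of the per-bp value (bp x depth)."""
        return float(np.dot(self.values, (self.ends - self.starts).astype(float)))

    @classmethod
    def from_intervals(
        cls,
        chrom: str,
        intervals: Iterable[tuple[int, int, float]],
        peak: float | None = None,
    ) -> "CoverageTrack":
        ivs = list(intervals)
        if ivs:
            starts, ends, values = (np.array(col) for col in zip(*ivs))
        else:
            starts = ends = values = np.array([])
        return cls(chrom, starts, ends, values, peak=peak)

    @classmethod
    def from_dense(
        cls, chrom: str, depth: np.ndarray, peak: float | None = None,
        keep_zero: bool = True,
    ) -> "CoverageTrack":
        """Run-length-encode a per-bp depth array starting at position 0.

        With ``keep_zero=False`` zero runs are dropped (implicit gaps, as
        ``bedtools genomecov`` without -bga would report).
        """
        depth = np.asarray(depth, dtype=float)
        if depth.size == 0:
            return cls(chrom, [], [], [], peak=peak)
        change = np.flatnonzero(depth[1:] != depth[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [depth.size]])
        values = depth[starts]
        if not keep_zero:
            nz = values != 0
            starts, ends, values = starts[nz], ends[nz], values[nz]
        return cls(chrom, starts, ends, values, peak=peak)

    def to_dense(self, length: int | None = None) -> np.ndarray:
        """Per-bp depth array over [0, length); gaps are 0."""
        n = self.span if length is None else length
        out = np.zeros(n, dtype=float)
        for s, e, v in zip(self.starts, self.ends, self.values):
            out[s:min(e, n)] = v
        return out

    def intervals(self) -> list[tuple[int, int, float]]:
        return [
            (int(s), int(e), float(v))
            for s, e, v in zip(self.starts, self.ends, self.values)
        ]


@dataclass
class UnionTrack:
    """Two tracks of one chromosome on a common interval partition.

    The intervals partition the union of both footprints; a bp covered by
    only one input carries 0 for the other.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values_a = np.asarray(self.values_a, dtype=np.float64)
        self.values_b = np.asarray(self.values_b, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.starts)

    def intervals(self) -> list[tuple[int, int, float, float]]:
        return [
            (int(s), int(e), float(a), float(b))
            for s, e, a, b in zip(self.starts, self.ends, self.values_a, self.values_b)
        ]


# ---------------------------------------------------------------------------
# BEDGRAPH

def read_bedgraph(path: str | Path) -> dict[str, CoverageTrack]:
    """Parse a 4-column BEDGRAPH into per-chromosome coverage tracks.

    ``track``/``browser`` lines and ``#`` comments are skipped. Intervals
    are sorted per chromosome; overlaps raise :class:`BedgraphFormatError`
    naming the offending line. Adjacent equal-value intervals are kept as-is.
    """
    chroms: dict[str, list[tuple[int, int, float, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedgraphFormatError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedgraphFormatError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            if end <= start:
                raise BedgraphFormatError(
                    f"{path}: line {lineno}: end <= start ({start} >= {end})"
                )
            if value < 0:
                raise BedgraphFormatError(
                    f"{path}: line {lineno}: negative coverage {value}"
                )
            chroms.setdefault(chrom, []).append((start, end, value, lineno))

    tracks: dict[str, CoverageTrack] = {}
    for chrom, rows in chroms.items():
        rows.sort(key=lambda r: r[0])
        for prev, cur in zip(rows, rows[1:]):
            if cur[0] < prev[1]:
                raise BedgraphFormatError(
                    f"{path}: line {cur[3]}: interval "
                    f"{chrom}:{cur[0]}-{cur[1]} overlaps a previous interval"
                )
        tracks[chrom] = CoverageTrack.from_intervals(
            chrom, [(s, e, v) for s, e, v, _ in rows]
        )
    return tracks


def write_bedgraph(
    tracks: Mapping[str, CoverageTrack] | CoverageTrack, path: str | Path
) -> None:
    """Write tracks as 4-column BEDGRAPH (chromosomes in mapping order)."""
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        for chrom, track in tracks.items():
            for s, e, v in zip(track.starts, track.ends, track.values):
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt_value(float(v))}\n")


def _fmt_value(v: float) -> str:
    return str(int(v)) if v == int(v) else repr(v)


def union_coverage(a: CoverageTrack, b: CoverageTrack) -> UnionTrack:
    """Lay two same-chromosome tracks onto a common partition.

    Every bp covered by a or b appears in exactly one output interval;
    a bp uncovered in one track carries 0 for that track. Per-track
    bp x value mass is conserved exactly.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"chromosome mismatch: {a.chrom!r} vs {b.chrom!r}")
    points = np.unique(np.concatenate([a.starts, a.ends, b.starts, b.ends]))
    if len(points) < 2:
        return UnionTrack(a.chrom, [], [], [], [])
    starts, ends = points[:-1], points[1:]
    va, ca = _values_at(a, starts)
    vb, cb = _values_at(b, starts)
    keep = ca | cb
    return UnionTrack(a.chrom, starts[keep], ends[keep], va[keep], vb[keep])


def _values_at(
    track: CoverageTrack, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(value, covered) of ``track`` at each position."""
    if len(track) == 0:
        z = np.zeros(len(positions))
        return z, np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(track.starts, positions, side="right") - 1
    covered = (idx >= 0) & (positions < track.ends[np.clip(idx, 0, None)])
    values = np.where(covered, track.values[np.clip(idx, 0, None)], 0.0)
    return values, covered


# ---------------------------------------------------------------------------
# BED

def write_bed(regions: Sequence, path: str | Path) -> None:
    """Write regions as BED (0-based half-open).

    Accepts any objects with ``chrom``/``start``/``end`` attributes or
    (chrom, start, end) tuples. A ``length`` attribute, when present, is
    written as the score column.
    """
    with open(path, "w") as fh:
        for r in regions:
            if isinstance(r, tuple):
                chrom, start, end = r[:3]
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                score = getattr(r, "length", None)
                cols = [r.chrom, str(r.start), str(r.end)]
                if score is not None:
                    cols += [f"{r.chrom}:{r.start}-{r.end}", str(score)]
                fh.write("\t".join(map(str, cols)) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Variants: VCF and the canonical allele-count table

def read_pool_vcf(
    path: str | Path, female_sample: str, male_sample: str
) -> list[PooledVariantSite]:
    """Read biallelic sites with per-sample allele depths from a VCF.

    The two pool samples are located by name; positions are converted to
    0-based. Sites without an AD annotation, or with more than one ALT
    allele, are skipped and the skip count logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        fem_idx = vcf.samples.index(female_sample)
        male_idx = vcf.samples.index(male_sample)
    except ValueError:
        raise ValueError(
            f"samples {female_sample!r}/{male_sample!r} not found in "
            f"{path} (has {vcf.samples})"
        ) from None

    sites: list[PooledVariantSite] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None or ad.shape[1] < 2:
            skipped += 1
            continue
        fem = np.clip(ad[fem_idx], 0, None)  # missing AD encodes as negative
        male = np.clip(ad[male_idx], 0, None)
        sites.append(
            PooledVariantSite(
                chrom=rec.CHROM,
                pos=rec.POS - 1,
                ref=rec.REF,
                alt=rec.ALT[0],
                fem_ref=int(fem[0]),
                fem_alt=int(fem[1]),
                male_ref=int(male[0]),
                male_alt=int(male[1]),
            )
        )
    if skipped:
        logger.warning("%s: skipped %d sites without usable AD", path, skipped)
    return sites


def write_pool_vcf(
    sites: Sequence[PooledVariantSite],
    path: str | Path,
    female_sample: str = "female_pool",
    male_sample: str = "male_pool",
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write sites as a minimal VCF 4.2 with GT:AD per pool sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolsex\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{female_sample}\t{male_sample}\n"
        )
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\t"
                f"GT:AD\t./.:{s.fem_ref},{s.fem_alt}\t./.:{s.male_ref},{s.male_alt}\n"
            )


def write_variant_table(sites: Sequence[PooledVariantSite], path: str | Path) -> None:
    """Write the canonical tab-separated allele-count table."""
    pd.DataFrame(
        [
            (s.chrom, s.pos, s.ref, s.alt, s.fem_ref, s.fem_alt, s.male_ref, s.male_alt)
            for s in sites
        ],
        columns=VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[PooledVariantSite]:
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PooledVariantSite(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            fem_ref=int(r.fem_ref), fem_alt=int(r.fem_alt),
            male_ref=int(r.male_ref), male_alt=int(r.male_alt),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Genotype tables (per-individual marker call x phenotypic sex)

def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a per-individual TSV of (individual, species, sex, marker).

    Sexes must be in {female, male} and marker calls in
    {positive, negative}; individual ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return validate_genotype_table(df[GENOTYPE_COLUMNS])


def validate_genotype_table(df: pd.DataFrame) -> pd.DataFrame:
    bad_sex = set(df["sex"]) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"unknown sex values {sorted(bad_sex)}")
    bad_marker = set(df["marker"]) - {"positive", "negative"}
    if bad_marker:
        raise ValueError(f"unknown marker values {sorted(bad_marker)}")
    if df["individual"].duplicated().any():
        dupes = df.loc[df["individual"].duplicated(), "individual"].tolist()
        raise ValueError(f"duplicate individual ids {dupes}")
    return df


def write_genotype_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_genotype_table(df)[GENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)
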