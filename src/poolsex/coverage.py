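"""Coverage-peak normalization and differential-coverage region calling.

The sex-specific signal sought here is a depth asymmetry: a W-specific
sequence sits at haploid depth (~0.5 of the diploid peak) in the female pool
and at (near) zero depth in the male pool. Both pools are first normalized
to diploid units — each pool's per-bp depth is divided by the mode of its
bp-mass depth histogram, so 1.0 means two-copy coverage — and candidate
regions are then maximal runs of base pairs where the opposite-sex pool is
at (or below) a ceiling and the target-sex pool above a floor. Nearby runs
are bridged (``bedtools merge -d`` semantics) and short blocks discarded,
which removes mismapping artifacts of the 100–200 bp scale.

The swapped-sex control repeats the call with the pool roles exchanged; a
specific signal yields hits in one direction only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from poolsex.io import CoverageTrack, UnionTrack, union_coverage

__all__ = [
    "RegionCallParams",
    "CandidateRegion",
    "SwappedControlReport",
    "estimate_diploid_peak",
    "normalize_track",
    "normalize_tracks",
    "call_differential_regions",
    "swapped_control",
]


@dataclass(frozen=True)
class RegionCallParams:
    """Thresholds of the differential-coverage region caller.

    max_opposite
        Normalized depth ceiling in the opposite-sex pool (inclusive;
        default 0 — "no coverage").
    min_target
        Normalized depth floor in the target-sex pool (strict; default 0.3,
        i.e. more than 30% of diploid coverage).
    merge_gap
        Blocks whose gap is <= this many bp are combined (default 30).
    min_len
        Minimum merged-block length in bp (default 160).
    min_len_strict
        If True the size filter is length > min_len instead of >= min_len.
    """

    max_opposite: float = 0.0
    min_target: float = 0.3
    merge_gap: int = 30
    min_len: int = 160
    min_len_strict: bool = False

    def __post_init__(self) -> None:
        if self.max_opposite < 0:
            raise ValueError("max_opposite must be >= 0")
        if not 0 < self.min_target <= 1:
            raise ValueError("min_target must be in (0, 1]")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")

    def passes_length(self, length: int) -> bool:
        return length > self.min_len if self.min_len_strict else length >= self.min_len


@dataclass
class CandidateRegion:
    """A merged differential-coverage block with per-pool summary means.

    Means are computed over the merged extent [start, end), counting
    uncovered bp as depth 0; ``n_blocks`` is the number of pre-merge blocks
    the region was combined from.
    """

    chrom: str
    start: int
    end: int
    mean_target: float
    mean_opposite: float
    n_blocks: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SwappedControlReport:
    """Region calls in the target direction and with pool roles swapped."""

    target_regions: list[CandidateRegion]
    control_regions: list[CandidateRegion]

    @property
    def n_target(self) -> int:
        return len(self.target_regions)

    @property
    def n_control(self) -> int:
        return len(self.control_regions)

    @property
    def target_bp(self) -> int:
        return sum(r.length for r in self.target_regions)

    @property
    def control_bp(self) -> int:
        return sum(r.length for r in self.control_regions)


# ---------------------------------------------------------------------------
# Normalization

def estimate_diploid_peak(
    tracks: Mapping[str, CoverageTrack] | CoverageTrack, bin_width: float = 1
) -> float:
    """Mode of the bp-mass depth histogram, excluding depth zero.

    Pool-seq depth along a mostly diploid genome is unimodal; the histogram
    bin holding the most base pairs is the diploid coverage peak used for
    normalization. Depth-0 bp (unsequenced gaps) are excluded; ties go to
    the lower depth, a conservative diploid estimate. Returns the lower edge
    of the winning bin (the depth itself for integer depths at bin_width 1).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.chrom: tracks}
    mass = np.zeros(0)
    for track in tracks.values():
        if len(track) == 0:
            continue
        bins = np.floor(track.values / bin_width).astype(np.int64)
        part = np.bincount(bins, weights=(track.ends - track.starts).astype(float))
        if part.size > mass.size:
            part[: mass.size] += mass
            mass = part
        else:
            mass[: part.size] += part
    if mass.size:
        mass[0] = 0.0  # depth-0 bin excluded
    if mass.sum() == 0:
        raise ValueError("no diploid peak: all coverage is zero")
    best = int(np.argmax(mass))  # argmax takes the first (lowest) bin on ties
    return float(best * bin_width)


def normalize_track(track: CoverageTrack, peak: float) -> CoverageTrack:
    """Divide every depth by ``peak`` so 1.0 = diploid coverage."""
    if peak <= 0:
        raise ValueError("peak must be > 0")
    return CoverageTrack(
        track.chrom, track.starts.copy(), track.ends.copy(),
        track.values / peak, peak=float(peak),
    )


def normalize_tracks(
    tracks: Mapping[str, CoverageTrack], peak: float | None = None,
    bin_width: float = 1,
) -> dict[str, CoverageTrack]:
    """Normalize a whole per-chromosome collection against one pool peak.

    The peak defaults to :func:`estimate_diploid_peak` over the collection.
    """
    if peak is None:
        peak = estimate_diploid_peak(tracks, bin_width=bin_width)
    return {c: normalize_track(t, peak) for c, t in tracks.items()}


# ---------------------------------------------------------------------------
# Region calling

def call_differential_regions(
    target: Mapping[str, CoverageTrack] | CoverageTrack,
    opposite: Mapping[str, CoverageTrack] | CoverageTrack,
    params: RegionCallParams | None = None,
) -> list[CandidateRegion]:
    """Call candidate sex-specific regions from two normalized tracks.

    Per bp, the predicate is ``opposite <= max_opposite AND target >
    min_target`` (bp uncovered by a track count as 0 for it). Maximal
    passing runs become blocks; blocks with inter-block gap <= merge_gap
    are merged transitively; merged blocks passing the size filter are
    returned sorted by coordinate. Chromosomes are processed independently;
    a chromosome absent from one input is treated as uncovered there.

    Both inputs must be normalized (carry peak metadata).
    """
    params = params or RegionCallParams()
    target_map = {target.chrom: target} if isinstance(target, CoverageTrack) else target
    opp_map = (
        {opposite.chrom: opposite} if isinstance(opposite, CoverageTrack) else opposite
    )
    for name, m in (("target", target_map), ("opposite", opp_map)):
        for track in m.values():
            if not track.is_normalized:
                raise ValueError(
                    f"{name} track {track.chrom!r} is not normalized "
                    "(no peak metadata); run normalize_track first"
                )

    regions: list[CandidateRegion] = []
    for chrom in sorted(set(target_map) | set(opp_map)):
        t = target_map.get(chrom, CoverageTrack(chrom, [], [], [], peak=1.0))
        o = opp_map.get(chrom, CoverageTrack(chrom, [], [], [], peak=1.0))
        regions.extend(_call_on_union(union_coverage(t, o), params))
    return regions


def _call_on_union(u: UnionTrack, params: RegionCallParams) -> list[CandidateRegion]:
    if len(u) == 0:
        return []
    passing = (u.values_b <= params.max_opposite) & (u.values_a > params.min_target)
    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return []
    p_starts, p_ends = u.starts[idx], u.ends[idx]

    # coalesce contiguous passing intervals into maximal runs (blocks)
    breaks = np.flatnonzero(p_starts[1:] != p_ends[:-1]) + 1
    b_starts = p_starts[np.concatenate([[0], breaks])]
    b_ends = p_ends[np.concatenate([breaks - 1, [len(p_ends) - 1]])]

    # transitive merge of blocks whose gaps are <= merge_gap
    gaps = b_starts[1:] - b_ends[:-1]
    cut = np.flatnonzero(gaps > params.merge_gap) + 1
    m_starts = b_starts[np.concatenate([[0], cut])]
    m_ends = b_ends[np.concatenate([cut - 1, [len(b_ends) - 1]])]
    m_nblocks = np.diff(np.concatenate([[0], cut, [len(b_starts)]]))

    # prefix sums over the union partition for summary means
    lengths = (u.ends - u.starts).astype(float)
    cum_a = np.concatenate([[0.0], np.cumsum(u.values_a * lengths)])
    cum_b = np.concatenate([[0.0], np.cumsum(u.values_b * lengths)])

    out: list[CandidateRegion] = []
    for s, e, nb in zip(m_starts, m_ends, m_nblocks):
        length = int(e - s)
        if not params.passes_length(length):
            continue
        lo = np.searchsorted(u.starts, s, side="left")
        hi = np.searchsorted(u.starts, e, side="left")
        out.append(
            CandidateRegion(
                chrom=u.chrom,
                start=int(s),
                end=int(e),
                mean_target=float(cum_a[hi] - cum_a[lo]) / length,
                mean_opposite=float(cum_b[hi] - cum_b[lo]) / length,
                n_blocks=int(nb),
            )
        )
    return out


def interval_jaccard(
    called: list[tuple[str, int, int]], truth: list[tuple[str, int, int]]
) -> float:
    """Intersection-over-union of two interval sets (bp-wise, per chrom).

    Used to score recovery of planted regions; 1.0 is exact recovery.
    Both sets empty gives 1.0 by convention.
    """
    def per_chrom(ivs):
        by: dict[str, set[int]] = {}
        for c, s, e in ivs:
            by.setdefault(c, set()).update(range(s, e))
        return by

    a, b = per_chrom(called), per_chrom(truth)
    inter = sum(len(a.get(c, set()) & b.get(c, set())) for c in set(a) | set(b))
    union = sum(len(a.get(c, set()) | b.get(c, set())) for c in set(a) | set(b))
    return inter / union if union else 1.0


def swapped_control(
    female: Mapping[str, CoverageTrack] | CoverageTrack,
    male: Mapping[str, CoverageTrack] | CoverageTrack,
    params: RegionCallParams | None = None,
    target_sex: str = "female",
) -> SwappedControlReport:
    """Run the region caller in both directions for specificity assessment.

    ``target_regions`` are called with the target sex as the high-coverage
    pool; ``control_regions`` repeat the call with the pool roles swapped.
    A genuine sex-specific signal appears only in the target direction;
    hits in the control direction measure the caller's false-positive
    behaviour under the same thresholds.
    """
    if target_sex not in ("female", "male"):
        raise ValueError("target_sex must be 'female' or 'male'")
    t, o = (female, male) if target_sex == "female" else (male, female)
    return SwappedControlReport(
        target_regions=call_differential_regions(t, o, params),
        control_regions=call_differential_regions(o, t, params),
    )
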