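"""Peak normalization and the differential-coverage region caller."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolsex.coverage import (
    CandidateRegion,
    RegionCallParams,
    call_differential_regions,
    estimate_diploid_peak,
    interval_jaccard,
    normalize_track,
    swapped_control,
)
from poolsex.io import CoverageTrack

from conftest import brute_force_regions, dense_to_track, random_dense_profile


def track(intervals, chrom="c", peak=1.0):
    return CoverageTrack.from_intervals(chrom, intervals, peak=peak)


class TestDiploidPeak:
    def test_constant_depth(self):
        t = track([(0, 1000, 40)], peak=None)
        assert estimate_diploid_peak(t) == 40

    def test_bp_mass_histogram_mode(self):
        """600 bp at 40x outweighs 300 bp at 20x and 100 bp at 80x."""
        t = track([(0, 300, 20), (300, 900, 40), (900, 1000, 80)], peak=None)
        assert estimate_diploid_peak(t) == 40

    def test_zero_bin_excluded(self):
        t = track([(0, 10_000, 0), (10_000, 10_100, 35)], peak=None)
        assert estimate_diploid_peak(t) == 35

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no diploid peak"):
            estimate_diploid_peak(track([(0, 100, 0)], peak=None))

    def test_tie_broken_toward_lower_depth(self):
        t = track([(0, 100, 30), (100, 200, 50)], peak=None)
        assert estimate_diploid_peak(t) == 30

    def test_bin_width_groups_depths(self):
        t = track([(0, 60, 41), (60, 120, 42), (120, 170, 10)], peak=None)
        assert estimate_diploid_peak(t, bin_width=5) == 40  # bin [40,45) wins


class TestNormalize:
    @pytest.mark.parametrize("value,peak,expected", [(42, 42, 1.0), (21, 42, 0.5), (0, 42, 0.0)])
    def test_values_divided_by_peak(self, value, peak, expected):
        out = normalize_track(track([(0, 10, value)], peak=None), peak)
        assert out.values[0] == pytest.approx(expected)
        assert out.peak == peak

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            normalize_track(track([(0, 10, 5)], peak=None), 0)

    def test_normalized_histogram_mode_is_one(self, rng):
        """After dividing by the estimated peak, the bp-mass mode falls in
        the bin containing 1.0."""
        dense = rng.poisson(42.0, size=50_000).astype(float)
        raw = CoverageTrack.from_dense("c", dense)
        peak = estimate_diploid_peak(raw)
        norm = normalize_track(raw, peak)
        scaled = CoverageTrack("c", norm.starts, norm.ends, norm.values * peak)
        assert estimate_diploid_peak(scaled) == peak  # same bin, rescaled


class TestRegionCallExamples:
    def test_single_differential_window(self):
        t = track([(0, 1000, 0.5)])
        o = track([(0, 200, 1.0), (200, 900, 0.0), (900, 1000, 1.0)])
        regions = call_differential_regions(t, o)
        assert [(r.start, r.end) for r in regions] == [(200, 900)]
        assert regions[0].length == 700
        assert regions[0].mean_target == pytest.approx(0.5)
        assert regions[0].mean_opposite == pytest.approx(0.0)

    def test_identical_tracks_give_nothing(self):
        t = track([(0, 5000, 1.0)])
        assert call_differential_regions(t, t) == []

    def test_merge_within_gap(self):
        """Blocks (100,200) and (225,400): gap 25 <= 30 merges them."""
        t = track([(100, 200, 0.5), (225, 400, 0.5)])
        o = track([], chrom="c")
        regions = call_differential_regions(t, o)
        assert [(r.start, r.end, r.n_blocks) for r in regions] == [(100, 400, 2)]

    def test_gap_beyond_merge_distance_splits(self):
        """Gap 31 > 30: the 100 bp block fails the size filter, the 169 bp
        block survives alone."""
        t = track([(100, 200, 0.5), (231, 400, 0.5)])
        o = track([], chrom="c")
        regions = call_differential_regions(t, o)
        assert [(r.start, r.end) for r in regions] == [(231, 400)]

    def test_min_target_is_strict(self):
        t = track([(0, 1000, 0.3)])
        o = track([], chrom="c")
        assert call_differential_regions(t, o) == []
        t2 = track([(0, 1000, 0.30001)])
        assert len(call_differential_regions(t2, o)) == 1

    def test_max_opposite_is_inclusive(self):
        t = track([(0, 1000, 0.5)])
        o = track([(0, 1000, 0.0)])
        assert len(call_differential_regions(t, o)) == 1

    def test_size_filter_boundary_inclusive_by_default(self):
        t = track([(0, 160, 0.5)])
        o = track([], chrom="c")
        assert len(call_differential_regions(t, o)) == 1
        strict = RegionCallParams(min_len_strict=True)
        assert call_differential_regions(t, o, strict) == []

    def test_unnormalized_input_rejected(self):
        t = track([(0, 1000, 21)], peak=None)
        o = track([(0, 1000, 0)], peak=None)
        with pytest.raises(ValueError, match="not normalized"):
            call_differential_regions(t, o)

    def test_chromosomes_processed_independently(self):
        t = {
            "c1": track([(0, 200, 0.5)], chrom="c1"),
            "c2": track([(0, 200, 0.5)], chrom="c2"),
        }
        o = {
            "c1": track([(0, 200, 0.0)], chrom="c1"),
            "c2": track([(0, 200, 1.0)], chrom="c2"),
        }
        regions = call_differential_regions(t, o)
        assert [r.chrom for r in regions] == ["c1"]


VALUE_SETS = (0.0, 0.1, 0.3, 0.31, 0.5, 1.0)


class TestRegionCallOracle:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        merge_gap=st.sampled_from([0, 5, 30]),
        min_len=st.sampled_from([1, 40, 160]),
        max_opposite=st.sampled_from([0.0, 0.1]),
        keep_zero=st.booleans(),
        strict=st.booleans(),
    )
    def test_matches_per_bp_oracle(self, seed, merge_gap, min_len, max_opposite,
                                   keep_zero, strict):
        """filter -> merge -> size-select equals the per-bp brute force on
        random piecewise-constant profiles, for implicit and explicit
        zero-coverage gaps alike."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 2000))
        td = random_dense_profile(rng, n, VALUE_SETS)
        od = random_dense_profile(rng, n, VALUE_SETS)
        params = RegionCallParams(max_opposite=max_opposite, merge_gap=merge_gap,
                                  min_len=min_len, min_len_strict=strict)
        got = call_differential_regions(
            dense_to_track("c", td, keep_zero=keep_zero),
            dense_to_track("c", od, keep_zero=keep_zero),
            params,
        )
        assert [(r.start, r.end) for r in got] == brute_force_regions(td, od, params)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_output_interval_invariants(self, seed):
        """Sorted, non-overlapping, pairwise gaps > merge_gap, lengths pass
        the size filter, and means respect the thresholds."""
        rng = np.random.default_rng(seed)
        td = random_dense_profile(rng, 3000, VALUE_SETS)
        od = random_dense_profile(rng, 3000, VALUE_SETS)
        params = RegionCallParams(min_len=50)
        regions = call_differential_regions(
            dense_to_track("c", td), dense_to_track("c", od), params
        )
        for r in regions:
            assert r.length >= params.min_len
            assert r.mean_target > 0
            # mean_opposite may exceed the per-bp ceiling only through
            # bridged gap bp, which are bounded by merge_gap per junction
            if r.n_blocks == 1:
                assert r.mean_opposite <= params.max_opposite + 1e-12
        for r1, r2 in zip(regions, regions[1:]):
            assert r2.start - r1.end > params.merge_gap

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotonicity_in_thresholds(self, seed):
        """Raising min_target never adds pre-merge bp; raising min_len never
        increases the region count."""
        rng = np.random.default_rng(seed)
        td = random_dense_profile(rng, 2000, VALUE_SETS)
        od = random_dense_profile(rng, 2000, VALUE_SETS)
        t, o = dense_to_track("c", td), dense_to_track("c", od)

        def base_bp(min_target):
            p = RegionCallParams(min_target=min_target, merge_gap=0, min_len=1)
            return sum(
                r.length for r in call_differential_regions(t, o, p)
            )

        assert base_bp(0.5) <= base_bp(0.3)

        def n_regions(min_len):
            p = RegionCallParams(min_len=min_len)
            return len(call_differential_regions(t, o, p))

        assert n_regions(300) <= n_regions(160) <= n_regions(40)


class TestBedtoolsMergeCrossCheck:
    def test_block_merging_matches_bedtools_merge_d(self, tmp_path, rng):
        """The transitive gap-merge reproduces `bedtools merge -d` on random
        block sets (independent oracle for the merge semantics)."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        for trial in range(10):
            pos = np.sort(rng.choice(5000, size=40, replace=False))
            blocks = [(int(s), int(e)) for s, e in zip(pos[::2], pos[1::2])]
            bed = tmp_path / f"blocks_{trial}.bed"
            bed.write_text("".join(f"c\t{s}\t{e}\n" for s, e in blocks))
            out = subprocess.run(
                ["bedtools", "merge", "-d", "30", "-i", str(bed)],
                capture_output=True, text=True, check=True,
            ).stdout
            expected = [
                (int(f[1]), int(f[2]))
                for f in (line.split("\t") for line in out.strip().splitlines())
            ]
            target = track([(s, e, 0.5) for s, e in blocks])
            got = call_differential_regions(
                target, track([], chrom="c"),
                RegionCallParams(merge_gap=30, min_len=1),
            )
            assert [(r.start, r.end) for r in got] == expected


class TestSwappedControl:
    def test_symmetric_scenario_gives_identical_counts(self):
        fem = track([(0, 500, 0.5), (500, 1000, 0.0)])
        male = track([(0, 500, 0.0), (500, 1000, 0.5)])
        rep = swapped_control(fem, male, RegionCallParams(min_len=100))
        assert rep.n_target == rep.n_control == 1
        assert rep.target_bp == rep.control_bp == 500

    def test_one_sided_signal_yields_empty_control(self):
        fem = track([(0, 1000, 1.0), (1000, 1400, 0.5), (1400, 2400, 1.0)])
        male = track([(0, 1000, 1.0), (1000, 1400, 0.0), (1400, 2400, 1.0)])
        rep = swapped_control(fem, male)
        assert [(r.start, r.end) for r in rep.target_regions] == [(1000, 1400)]
        assert rep.control_regions == []


class TestIntervalJaccard:
    def test_exact_and_partial_overlap(self):
        truth = [("c", 0, 100)]
        assert interval_jaccard([("c", 0, 100)], truth) == 1.0
        assert interval_jaccard([("c", 50, 150)], truth) == pytest.approx(50 / 150)
        assert interval_jaccard([], truth) == 0.0
        assert interval_jaccard([], []) == 1.0
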