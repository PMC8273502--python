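"""Shared fixtures and independent brute-force oracles.

The oracles re-derive results per base pair with plain Python/numpy loops
and never call the interval-based implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from poolsex.coverage import RegionCallParams
from poolsex.io import CoverageTrack


def brute_force_regions(
    target_dense: np.ndarray,
    opposite_dense: np.ndarray,
    params: RegionCallParams,
) -> list[tuple[int, int]]:
    """Literal per-bp filter -> merge -> size-select on dense depth arrays."""
    n = max(len(target_dense), len(opposite_dense))
    t = np.zeros(n)
    t[: len(target_dense)] = target_dense
    o = np.zeros(n)
    o[: len(opposite_dense)] = opposite_dense
    passing = (o <= params.max_opposite) & (t > params.min_target)

    blocks: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if passing[i]:
            j = i
            while j < n and passing[j]:
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1

    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s - merged[-1][1] <= params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    def keep(length: int) -> bool:
        return length > params.min_len if params.min_len_strict else length >= params.min_len

    return [(s, e) for s, e in merged if keep(e - s)]


def brute_force_union(a: CoverageTrack, b: CoverageTrack) -> list[tuple[int, int, float, float]]:
    """Per-bp union of two tracks, run-length compressed."""
    n = max(a.span, b.span)
    da, db = a.to_dense(n), b.to_dense(n)
    cov = np.zeros(n, dtype=bool)
    for tr in (a, b):
        for s, e, _ in tr.intervals():
            cov[s:e] = True
    out: list[tuple[int, int, float, float]] = []
    i = 0
    while i < n:
        if not cov[i]:
            i += 1
            continue
        j = i
        while j < n and cov[j] and da[j] == da[i] and db[j] == db[i]:
            j += 1
        out.append((i, j, float(da[i]), float(db[i])))
        i = j
    return out


def random_dense_profile(
    rng: np.random.Generator, length: int, values: tuple[float, ...]
) -> np.ndarray:
    """Piecewise-constant depth profile with geometric segment lengths."""
    out = np.empty(length)
    i = 0
    while i < length:
        seg = int(rng.geometric(1 / 40))
        out[i : i + seg] = rng.choice(values)
        i += seg
    return out


def dense_to_track(
    chrom: str, dense: np.ndarray, peak: float | None = 1.0, keep_zero: bool = True
) -> CoverageTrack:
    return CoverageTrack.from_dense(chrom, dense, peak=peak, keep_zero=keep_zero)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
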