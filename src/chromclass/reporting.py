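"""Summaries over called regions: signal distributions, cross-cell-line
sharing, and peak-in-region fractions.

Quantiles throughout are nearest-rank (the smallest value with at least the
requested fraction of observations at or below it), for exact
reproducibility across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
from itertools import combinations

import numpy as np

from .genome import (
    BinGrid,
    PeakSet,
    RegionSet,
    SignalTrack,
    bins_overlapping,
    intersect_intervals,
    total_bases,
)
from .hotlot import _nearest_rank


@dataclass
class DistStats:
    """Quartiles and outlier-trimmed summary of a signal distribution.

    Quartiles (nearest-rank) are computed before trimming; values outside
    [Q1 - 5 IQR, Q3 + 5 IQR] are excluded from the whiskers and the mean.
    """

    q1: float
    median: float
    q3: float
    mean: float
    whisker_low: float
    whisker_high: float
    n_kept: int
    n_trimmed: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def bounds(self) -> tuple[float, float]:
        return self.q1 - 5 * self.iqr, self.q3 + 5 * self.iqr


def dist_stats(values: np.ndarray, iqr_factor: float = 5.0) -> DistStats:
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty value set")
    s = np.sort(values)
    q1 = _nearest_rank(s, 0.25)
    med = _nearest_rank(s, 0.5)
    q3 = _nearest_rank(s, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
    kept = values[(values >= lo) & (values <= hi)]
    return DistStats(
        q1=q1, median=med, q3=q3,
        mean=float(kept.mean()),
        whisker_low=float(kept.min()),
        whisker_high=float(kept.max()),
        n_kept=int(len(kept)),
        n_trimmed=int(len(values) - len(kept)),
    )


def region_feature_stats(region: RegionSet, track: SignalTrack) -> DistStats:
    """Distribution of per-bin track values over a region set's bins."""
    if region.bin_indices is not None and len(region.bin_indices):
        idx = region.bin_indices
    else:
        idx = bins_overlapping(region.regions, track.grid)
    if len(idx) == 0:
        raise ValueError(f"region set {region.kind!r} is empty")
    return dist_stats(track.values[idx])


def sharing_by_count(
    region_sets: Mapping[str, RegionSet], grid: BinGrid
) -> tuple[dict[int, float], dict[tuple[str, ...], float]]:
    """Fractions of covered bins shared by exactly k cell lines, and by each
    of the 2^n - 1 cell-line combinations.  Both fraction sets sum to 1 over
    the union of covered bins."""
    cells = sorted(region_sets)
    masks = {}
    for cl in cells:
        rs = region_sets[cl]
        m = np.zeros(grid.n_bins, dtype=bool)
        idx = (
            rs.bin_indices
            if rs.bin_indices is not None
            else bins_overlapping(rs.regions, grid)
        )
        m[idx] = True
        masks[cl] = m
    union = np.zeros(grid.n_bins, dtype=bool)
    for m in masks.values():
        union |= m
    total = int(union.sum())
    if total == 0:
        return {}, {}
    counts = np.zeros(grid.n_bins, dtype=int)
    for m in masks.values():
        counts += m
    by_k = {
        k: float((counts == k).sum()) / total for k in range(1, len(cells) + 1)
    }
    by_combo: dict[tuple[str, ...], float] = {}
    stacked = np.vstack([masks[cl] for cl in cells])
    for r in range(1, len(cells) + 1):
        for combo in combinations(range(len(cells)), r):
            in_combo = np.ones(grid.n_bins, dtype=bool)
            for i in combo:
                in_combo &= stacked[i]
            for i in range(len(cells)):
                if i not in combo:
                    in_combo &= ~stacked[i]
            frac = float(in_combo.sum()) / total
            by_combo[tuple(cells[i] for i in combo)] = frac
    return by_k, by_combo


def _overlap_with_sorted(p, starts: np.ndarray, ends: np.ndarray) -> int:
    """Bases of interval p covered by a sorted, non-overlapping interval set."""
    i = int(np.searchsorted(ends, p.start, side="right"))
    ov = 0
    while i < len(starts) and starts[i] < p.end:
        ov += min(int(ends[i]), p.end) - max(int(starts[i]), p.start)
        i += 1
    return ov


def peak_region_fractions(
    peakset: PeakSet,
    region_sets: Mapping[str, RegionSet | Sequence],
    min_overlap_frac: float = 0.5,
) -> dict[str, float]:
    """Fraction of peaks lying within each region type.

    A peak is "within" a type if at least ``min_overlap_frac`` of its bases
    overlap that type's regions.  Empty peak sets give NaN fractions.
    """
    from .genome import normalize_intervals

    out = {}
    n = len(peakset.peaks)
    for name, rs in region_sets.items():
        regions = rs.regions if isinstance(rs, RegionSet) else list(rs)
        if n == 0:
            out[name] = float("nan")
            continue
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for iv in normalize_intervals(regions):
            by_chrom.setdefault(iv.chrom, ([], []))
            by_chrom[iv.chrom][0].append(iv.start)
            by_chrom[iv.chrom][1].append(iv.end)
        by_chrom = {
            c: (np.asarray(s), np.asarray(e)) for c, (s, e) in by_chrom.items()
        }
        hits = 0
        for p in peakset.peaks:
            se = by_chrom.get(p.chrom)
            if se is None:
                continue
            if _overlap_with_sorted(p, *se) >= min_overlap_frac * len(p):
                hits += 1
        out[name] = hits / n
    return out
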