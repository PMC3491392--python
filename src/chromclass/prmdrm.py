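"""Promoter-proximal and gene-distal regulatory module calling.

PRMs are called with the same cross-validated classifier machinery as BARs,
but with positives at the TSS bins of expressed transcripts and a composite
negative set (non-binding bins, gene-distal non-POL2RA peak bins, and
TSS-flank bins without peaks).  The PRM threshold is the order statistic
leaving exactly 1% of held-out negatives above it, averaged over folds.
DRMs are non-PRM BAR bins at least 10 kbp from any gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .barbir import ScoreTrack
from .genome import (
    Annotation,
    BinGrid,
    Interval,
    PeakSet,
    RegionSet,
    bins_overlapping,
    distance_to_features,
)

RNA_ASSAYS = ("polyA+ RNA-seq", "polyA- RNA-seq", "short RNA-seq")
TAG_ASSAYS = ("polyA+ CAGE", "diTag")


def expressed_transcripts(
    expression: pd.DataFrame,
    cell_line: str,
    rpkm_min: float = 1.0,
    rpm_min: float = 1.0,
    rna_assays: Sequence[str] = RNA_ASSAYS,
    tag_assays: Sequence[str] = TAG_ASSAYS,
) -> set[str]:
    """Transcripts expressed in a cell line: >= rpkm_min in any RNA-seq assay
    OR >= rpm_min in any CAGE/diTag assay (both thresholds inclusive)."""
    if cell_line not in expression.columns.get_level_values("cell_line"):
        raise KeyError(f"cell line {cell_line!r} absent from expression matrix")
    sub = expression[cell_line]
    ok = pd.Series(False, index=expression.index)
    for a in rna_assays:
        if a in sub.columns:
            ok |= sub[a] >= rpkm_min
    for a in tag_assays:
        if a in sub.columns:
            ok |= sub[a] >= rpm_min
    return set(expression.index[ok])


def expressed_tss_bins(
    annotation: Annotation,
    expression: pd.DataFrame,
    grid: BinGrid,
    cell_line: str,
    rpkm_min: float = 1.0,
    rpm_min: float = 1.0,
) -> np.ndarray:
    """Bins containing the TSS of any expressed transcript (positives)."""
    expr = expressed_transcripts(expression, cell_line, rpkm_min, rpm_min)
    idx = {
        grid.bin_index(t.chrom, t.tss)
        for t in annotation.transcripts
        if t.transcript_id in expr
    }
    return np.array(sorted(idx), dtype=np.int64)


def tss_flank_bins(
    annotation: Annotation,
    grid: BinGrid,
    upstream: tuple[int, int] = (1000, 5000),
    downstream: tuple[int, int] = (200, 1000),
) -> np.ndarray:
    """Bins in the strand-aware TSS-flank windows (upstream 1-5 kb,
    downstream 0.2-1 kb by default)."""
    out: set[int] = set()
    for t in annotation.transcripts:
        length = grid.genome.length(t.chrom)
        tss = t.tss
        if t.strand == "+":
            windows = [
                (tss - upstream[1], tss - upstream[0]),
                (tss + downstream[0], tss + downstream[1]),
            ]
        else:
            windows = [
                (tss + upstream[0], tss + upstream[1]),
                (tss - downstream[1], tss - downstream[0]),
            ]
        for s, e in windows:
            s, e = max(0, s), min(length, e)
            if s < e:
                out.update(int(i) for i in grid.bins_in_range(t.chrom, s, e))
    return np.array(sorted(out), dtype=np.int64)


@dataclass
class NegativeBins:
    """The three labeled PRM negative subsets."""

    no_binding: np.ndarray
    distal_peaks: np.ndarray
    tss_flank: np.ndarray

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.no_binding, self.distal_peaks, self.tss_flank])


def prm_negative_bins(
    grid: BinGrid,
    peaksets: Sequence[PeakSet],
    annotation: Annotation,
    n_neg: int = 5000,
    min_gene_dist: int = 10_000,
    pol2_name: str = "POL2RA",
    seed: int = 0,
) -> NegativeBins:
    """Sample the three PRM negative subsets in equal thirds.

    1. bins overlapping no TRF peak anywhere;
    2. bins in peaks of TRFs other than POL2RA at least ``min_gene_dist``
       from any gene (union transcript span per gene);
    3. peak-free bins in the TSS-flank windows.
    """
    rng = np.random.default_rng(seed)
    all_peak_bins = bins_overlapping(
        [p for ps in peaksets for p in ps.peaks], grid
    )
    peak_mask = np.zeros(grid.n_bins, dtype=bool)
    peak_mask[all_peak_bins] = True

    sub1 = np.flatnonzero(~peak_mask)

    gene_spans = annotation.gene_spans()
    nonpol2_bins = bins_overlapping(
        [p for ps in peaksets if ps.trf != pol2_name for p in ps.peaks], grid
    )
    if len(nonpol2_bins):
        ivs = [grid.bin_interval(int(i)) for i in nonpol2_bins]
        d = distance_to_features(ivs, gene_spans)
        sub2 = nonpol2_bins[d >= min_gene_dist]
    else:
        sub2 = np.empty(0, dtype=np.int64)

    flank = tss_flank_bins(annotation, grid)
    sub3 = flank[~peak_mask[flank]]

    empties = [
        name
        for name, s in (("no_binding", sub1), ("distal_peaks", sub2), ("tss_flank", sub3))
        if len(s) == 0
    ]
    if empties:
        raise ValueError(f"empty PRM negative subset(s): {', '.join(empties)}")

    third = n_neg // 3
    def draw(pool: np.ndarray, n: int) -> np.ndarray:
        if len(pool) <= n:
            return np.sort(pool)
        return np.sort(rng.choice(pool, size=n, replace=False))

    return NegativeBins(
        no_binding=draw(sub1, n_neg - 2 * third),
        distal_peaks=draw(sub2, third),
        tss_flank=draw(sub3, third),
    )


def prm_threshold(
    fold_negative_scores: Sequence[np.ndarray],
    fraction: float = 0.01,
    pooled: bool = False,
) -> float:
    """Score threshold with exactly ``fraction`` of negatives above it.

    Per fold, the threshold is the smallest score value with
    ``floor(fraction * N)`` negatives strictly above it (ties resolve toward
    fewer than the target above); the returned threshold is the mean over
    folds.  With ``pooled=True`` the rule is applied once to all negatives.
    """
    lists = [np.asarray(s, dtype=float) for s in fold_negative_scores]
    if pooled:
        lists = [np.concatenate(lists)]
    thresholds = []
    for s in lists:
        n = len(s)
        if n < 100:
            raise ValueError(f"need >= 100 negative scores per fold, got {n}")
        k = int(np.floor(fraction * n))
        s_sorted = np.sort(s)
        t = float(s_sorted[n - k - 1]) if k > 0 else float(s_sorted[-1])
        if k > 0 and np.count_nonzero(s > t) == 0:
            warnings.warn("tied negative scores: no negatives above threshold")
        thresholds.append(t)
    return float(np.mean(thresholds))


def call_prms(
    score_track: ScoreTrack, threshold: float, cell_line: str = ""
) -> RegionSet:
    """PRM bins: average PRM score strictly higher than the threshold."""
    idx = np.flatnonzero(score_track.scores > threshold)
    return RegionSet.from_bins(
        score_track.grid, idx, kind="PRM",
        cell_line=cell_line or score_track.cell_line,
        scores=score_track.scores[idx],
    )


def call_drms(
    bars: RegionSet,
    prms: RegionSet,
    annotation: Annotation,
    min_dist: int = 10_000,
) -> RegionSet:
    """DRM bins: non-PRM BAR bins >= min_dist bp from any gene span."""
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    grid = bars.grid
    if grid is None:
        raise ValueError("BAR region set must carry its grid and bin indices")
    bar_bins = bars.bin_indices
    prm_bins = prms.bin_index_set() if prms.bin_indices is not None else set()
    keep = np.array([b for b in bar_bins if int(b) not in prm_bins], dtype=np.int64)
    if len(keep) == 0:
        return RegionSet.from_bins(grid, keep, kind="DRM", cell_line=bars.cell_line)
    spans = annotation.gene_spans()
    ivs = [grid.bin_interval(int(i)) for i in keep]
    d = distance_to_features(ivs, spans)
    keep = keep[d >= min_dist]
    return RegionSet.from_bins(grid, keep, kind="DRM", cell_line=bars.cell_line)
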