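"""Enhancer candidate generation: two rounds of filter chains.

Round 1 ranks conserved, motif-dense binding-active regions away from
promoters and exons.  Round 2 intersects a BAR-based filter chain with a
two-stage binding-site predictor (window-level aggregate features, then
signal-shape profiles), and refines the intersection to 100-700 bp
fragments with high H3K4me1/H3K4me3.

Every exclusion is recorded in a :class:`FilterChainReport` so the chain is
auditable step by step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .barbir import ForestBinClassifier, ScoreTrack
from .genome import (
    Annotation,
    BinGrid,
    Interval,
    PeakSet,
    RegionSet,
    SignalTrack,
    bins_overlapping,
    intersect_intervals,
    merge_intervals,
    normalize_intervals,
)


@dataclass
class FilterChainReport:
    """Ordered audit of a filter chain: (name, items in, items out)."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append((name, n_in, n_out))

    def as_rows(self) -> list[dict]:
        return [{"filter": n, "n_in": i, "n_out": o} for n, i, o in self.steps]


def _tss_window_bins(
    annotation: Annotation, grid: BinGrid, upstream: int, downstream: int,
    strand_aware: bool = True,
) -> np.ndarray:
    """Bins overlapping [TSS - upstream, TSS + downstream) (strand-aware)."""
    out: set[int] = set()
    for t in annotation.transcripts:
        length = grid.genome.length(t.chrom)
        if not strand_aware or t.strand == "+":
            s, e = t.tss - upstream, t.tss + downstream
        else:
            s, e = t.tss - downstream + 1, t.tss + upstream + 1
        s, e = max(0, s), min(length, e)
        if s < e:
            out.update(int(i) for i in grid.bins_in_range(t.chrom, s, e))
    return np.array(sorted(out), dtype=np.int64)


def _near_exon_bins(annotation: Annotation, grid: BinGrid, margin: int) -> np.ndarray:
    out: set[int] = set()
    for iv in annotation.exon_intervals():
        length = grid.genome.length(iv.chrom)
        s, e = max(0, iv.start - margin), min(length, iv.end + margin)
        out.update(int(i) for i in grid.bins_in_range(iv.chrom, s, e))
    return np.array(sorted(out), dtype=np.int64)


def _motif_count(region: Interval, sites: Sequence[Interval]) -> int:
    return sum(1 for s in sites if s.overlaps(region))


def round1_candidates(
    bars: RegionSet,
    annotation: Annotation,
    conservation: SignalTrack,
    motif_sites: Mapping[str, Sequence[Interval]],
    tss_upstream: int = 2000,
    tss_downstream: int = 500,
    exon_margin: int = 1000,
    conservation_top: float = 0.02,
    size_range: tuple[int, int] = (800, 4000),
    top_k: int = 50,
) -> tuple[RegionSet, FilterChainReport]:
    """Round-1 chain: TSS/exon exclusion, top conservation, size filter,
    then ranking by binding-motif density."""
    grid = conservation.grid
    report = FilterChainReport()
    bins = np.asarray(bars.bin_indices, dtype=np.int64)

    mask = np.zeros(grid.n_bins, dtype=bool)
    mask[bins] = True
    n0 = int(mask.sum())
    tssb = _tss_window_bins(annotation, grid, tss_upstream, tss_downstream)
    mask[tssb] = False
    report.record("tss_flank_exclusion", n0, int(mask.sum()))

    n0 = int(mask.sum())
    exb = _near_exon_bins(annotation, grid, exon_margin)
    mask[exb] = False
    report.record("exon_margin_exclusion", n0, int(mask.sum()))

    surviving = np.flatnonzero(mask)
    n0 = len(surviving)
    if n0 == 0:
        return RegionSet(kind="enhancer_r1", cell_line=bars.cell_line, grid=grid), report
    cons = conservation.values[surviving]
    k = max(1, int(np.floor(conservation_top * n0)))
    order = np.argsort(-cons, kind="stable")
    keep = np.sort(surviving[order[:k]])
    report.record("conservation_top_fraction", n0, len(keep))

    regions = merge_intervals([grid.bin_interval(int(i)) for i in keep], max_gap=0)
    n0 = len(regions)
    sized = [r for r in regions if size_range[0] <= len(r) <= size_range[1]]
    report.record("size_filter", n0, len(sized))

    all_sites = [s for sites in motif_sites.values() for s in sites]
    density = np.array(
        [_motif_count(r, all_sites) / len(r) for r in sized]
    ) if sized else np.empty(0)
    order = np.argsort(-density, kind="stable")
    ranked = [sized[int(i)] for i in order[:top_k]]
    report.record("motif_density_top_k", len(sized), len(ranked))
    return (
        RegionSet(kind="enhancer_r1", regions=ranked, cell_line=bars.cell_line, grid=grid),
        report,
    )


def round2_method1(
    bars: RegionSet,
    prm_scores: ScoreTrack,
    annotation: Annotation,
    conservation: SignalTrack,
    motif_sites: Mapping[str, Sequence[Interval]],
    expressed_trfs: Sequence[str] | None = None,
    prm_score_max: float = 0.8,
    tss_margin: int = 2000,
    conservation_min: float = 0.1,
) -> tuple[RegionSet, FilterChainReport]:
    """BAR filter chain: drop promoter-like, TSS-near, exonic and
    unconserved bins, merge, then require a motif of an expressed TRF."""
    grid = prm_scores.grid
    report = FilterChainReport()
    mask = np.zeros(grid.n_bins, dtype=bool)
    mask[np.asarray(bars.bin_indices, dtype=np.int64)] = True

    n0 = int(mask.sum())
    mask &= ~(prm_scores.scores > prm_score_max)
    report.record("promoter_score", n0, int(mask.sum()))

    n0 = int(mask.sum())
    tssb = _tss_window_bins(annotation, grid, tss_margin, tss_margin, strand_aware=False)
    mask[tssb] = False
    report.record("tss_margin", n0, int(mask.sum()))

    n0 = int(mask.sum())
    exb = bins_overlapping(annotation.exon_intervals(), grid)
    mask[exb] = False
    report.record("exon_overlap", n0, int(mask.sum()))

    n0 = int(mask.sum())
    mask &= ~(conservation.values < conservation_min)
    report.record("conservation_min", n0, int(mask.sum()))

    regions = merge_intervals(
        [grid.bin_interval(int(i)) for i in np.flatnonzero(mask)], max_gap=0
    )
    n0 = len(regions)
    trfs = list(motif_sites) if expressed_trfs is None else list(expressed_trfs)
    sites = [s for t in trfs for s in motif_sites.get(t, [])]
    kept = [r for r in regions if _motif_count(r, sites) > 0]
    report.record("expressed_trf_motif_presence", n0, len(kept))
    return (
        RegionSet(kind="enhancer_m1", regions=kept, cell_line=bars.cell_line, grid=grid),
        report,
    )


# -- round 2, method 2: two-stage binding-site predictor ---------------------


def _window_grid(grid: BinGrid, window_bins: int) -> list[tuple[str, int, int]]:
    """Non-overlapping windows of `window_bins` bins per chromosome."""
    out = []
    for chrom in grid.genome.chrom_names:
        n = grid.chrom_nbins(chrom)
        length = grid.genome.length(chrom)
        for w0 in range(0, n - window_bins + 1, window_bins):
            s = w0 * grid.width
            e = min((w0 + window_bins) * grid.width, length)
            out.append((chrom, s, e))
    return out


def _window_features(
    tracks: Sequence[SignalTrack], grid: BinGrid, windows: list[tuple[str, int, int]],
    aggregate: bool,
) -> np.ndarray:
    """Aggregate (mean) or profile (per-sub-bin) features for each window."""
    rows = []
    for chrom, s, e in windows:
        idx = grid.bins_in_range(chrom, s, e)
        if aggregate:
            rows.append([float(t.values[idx].mean()) for t in tracks])
        else:
            rows.append(np.concatenate([t.values[idx] for t in tracks]))
    return np.asarray(rows, dtype=float)


def round2_method2(
    feature_tracks: Sequence[SignalTrack],
    peaksets: Sequence[PeakSet],
    annotation: Annotation,
    grid: BinGrid,
    repeats: Sequence[Interval] = (),
    window_bins: int = 10,
    stage1_cutoff: float = 0.5,
    stage2_cutoff: float = 0.5,
    tss_margin: int = 2000,
    involve_marks: tuple[str, ...] = ("H3K4me1", "H3K4me3"),
    involve_min: float = 2.0,
    n_train: int = 2000,
    seed: int = 0,
    cell_line: str = "",
) -> tuple[RegionSet, FilterChainReport]:
    """Two-stage predictor of active binding regions.

    Stage 1 scores 1-kb windows on aggregate (mean) feature values, trained
    on peak-overlapping vs random peak-free windows.  Stage 2 re-scores
    stage-1 survivors on the signal profile across the window's 100-bp
    sub-bins, trained on peak-centred windows vs windows offset by 1 kb.
    Survivors are filtered for repeats, exon/TSS proximity, and must involve
    one of the given marks (window mean above ``involve_min``).
    """
    rng = np.random.default_rng(seed)
    report = FilterChainReport()
    windows = _window_grid(grid, window_bins)
    win_iv = [Interval(c, s, e) for c, s, e in windows]
    all_peaks = normalize_intervals([p for ps in peaksets for p in ps.peaks])
    peak_mask = np.zeros(grid.n_bins, dtype=bool)
    peak_mask[bins_overlapping(all_peaks, grid)] = True
    overlaps_peak = np.array(
        [peak_mask[grid.bins_in_range(c, s, e)].any() for c, s, e in windows]
    )

    pos_idx = np.flatnonzero(overlaps_peak)
    neg_idx = np.flatnonzero(~overlaps_peak)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("cannot build stage-1 training split: one class empty")
    n_each = min(n_train // 2, len(pos_idx), len(neg_idx))
    tr_pos = rng.choice(pos_idx, size=n_each, replace=False)
    tr_neg = rng.choice(neg_idx, size=n_each, replace=False)

    X1 = _window_features(feature_tracks, grid, windows, aggregate=True)
    clf1 = ForestBinClassifier(seed=seed)
    clf1.fit(
        np.vstack([X1[tr_pos], X1[tr_neg]]),
        np.concatenate([np.ones(n_each, int), np.zeros(n_each, int)]),
    )
    s1 = clf1.score_bins(X1)
    stage1_pass = s1 > stage1_cutoff
    report.record("stage1_window_score", len(windows), int(stage1_pass.sum()))

    # stage 2: peak-centred windows vs 1-kb-offset flanks
    window_len = window_bins * grid.width
    half = window_len // 2
    pos_windows, neg_windows = [], []
    width = grid.width
    for p in all_peaks:
        c = (p.start + p.end) // 2
        length = grid.genome.length(p.chrom)
        # snap to bin boundaries so every profile has the same sub-bin count
        s = min(max(0, c - half), length - window_len) // width * width
        pos_windows.append((p.chrom, s, s + window_len))
        off = window_len if rng.random() < 0.5 else -window_len
        s2 = min(max(0, s + off), length - window_len) // width * width
        neg_windows.append((p.chrom, s2, s2 + window_len))
    Xp = _window_features(feature_tracks, grid, pos_windows, aggregate=False)
    Xn = _window_features(feature_tracks, grid, neg_windows, aggregate=False)
    clf2 = ForestBinClassifier(seed=seed + 1)
    clf2.fit(
        np.vstack([Xp, Xn]),
        np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xn), int)]),
    )
    # candidates are re-centred on their strongest sub-bin so their profiles
    # align with the peak-centred training windows
    combined = np.sum([t.values for t in feature_tracks], axis=0)
    cand_windows = []
    for i in np.flatnonzero(stage1_pass):
        chrom, s, e = windows[int(i)]
        idx = grid.bins_in_range(chrom, s, e)
        b_star = int(idx[np.argmax(combined[idx])])
        _, bs, _ = grid.bin_bounds(b_star)
        length = grid.genome.length(chrom)
        cs = min(max(0, bs + grid.width // 2 - half), length - window_len)
        cs = cs // width * width
        cand_windows.append((chrom, cs, cs + window_len))
    X2 = _window_features(feature_tracks, grid, cand_windows, aggregate=False)
    s2_scores = clf2.score_bins(X2) if len(X2) else np.empty(0)
    keep = np.flatnonzero(stage1_pass)[s2_scores > stage2_cutoff]
    report.record("stage2_profile_score", int(stage1_pass.sum()), len(keep))

    kept_iv = [win_iv[int(i)] for i in keep]
    n0 = len(kept_iv)
    rep_mask = np.zeros(grid.n_bins, dtype=bool)
    if len(list(repeats)):
        rep_mask[bins_overlapping(list(repeats), grid)] = True
    kept_iv = [
        w for w in kept_iv
        if not rep_mask[grid.bins_in_range(w.chrom, w.start, w.end)].any()
    ]
    report.record("repeat_removal", n0, len(kept_iv))

    n0 = len(kept_iv)
    tssb = set(
        int(i) for i in _tss_window_bins(annotation, grid, tss_margin, tss_margin, False)
    )
    exb = set(int(i) for i in bins_overlapping(annotation.exon_intervals(), grid))
    bad = tssb | exb
    kept_iv = [
        w for w in kept_iv
        if not any(int(i) in bad for i in grid.bins_in_range(w.chrom, w.start, w.end))
    ]
    report.record("exon_tss_filter", n0, len(kept_iv))

    n0 = len(kept_iv)
    mark_tracks = [t for t in feature_tracks if t.assay in involve_marks]
    final = []
    for w in kept_iv:
        idx = grid.bins_in_range(w.chrom, w.start, w.end)
        if any(float(t.values[idx].mean()) > involve_min for t in mark_tracks):
            final.append(w)
    report.record("involves_h3k4_mark", n0, len(final))
    merged = merge_intervals(final, max_gap=0)
    return (
        RegionSet(kind="enhancer_m2", regions=merged, cell_line=cell_line, grid=grid),
        report,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, cw[-1] / 2.0)])


def _per_base_median(region: Interval, track: SignalTrack) -> float:
    grid = track.grid
    idx = grid.bins_in_range(region.chrom, region.start, region.end)
    off = grid.chrom_offset(region.chrom)
    starts = (idx - off) * grid.width
    ends = np.minimum(starts + grid.width, grid.genome.length(region.chrom))
    cover = np.minimum(ends, region.end) - np.maximum(starts, region.start)
    return _weighted_median(track.values[idx], cover.astype(float))


def combine_and_refine(
    list_a: RegionSet,
    list_b: RegionSet,
    h3k4me1: SignalTrack,
    h3k4me3: SignalTrack,
    min_len: int = 100,
    max_len: int = 700,
    median_min: float = 5.0,
) -> tuple[RegionSet, FilterChainReport]:
    """Intersect the two candidate lists and refine to 100-700 bp
    high-confidence fragments (median H3K4me1 or H3K4me3 strictly > 5)."""
    report = FilterChainReport()
    inter = intersect_intervals(list_a.regions, list_b.regions)
    report.record("intersection", len(list_a.regions) + len(list_b.regions), len(inter))

    n0 = len(inter)
    inter = [iv for iv in inter if len(iv) >= min_len]
    report.record("min_length", n0, len(inter))

    grid = h3k4me1.grid
    refined = []
    for iv in inter:
        if len(iv) <= max_len:
            refined.append(iv)
            continue
        # trim symmetrically about the signal-weighted centre
        idx = grid.bins_in_range(iv.chrom, iv.start, iv.end)
        off = grid.chrom_offset(iv.chrom)
        centers = (idx - off) * grid.width + grid.width / 2.0
        w = h3k4me1.values[idx] + h3k4me3.values[idx]
        c = float(np.average(centers, weights=w)) if w.sum() > 0 else (iv.start + iv.end) / 2
        s = int(round(c - max_len / 2))
        s = min(max(s, iv.start), iv.end - max_len)
        refined.append(Interval(iv.chrom, s, s + max_len))
    report.record("max_length_trim", len(inter), len(refined))

    n0 = len(refined)
    final = [
        iv for iv in refined
        if _per_base_median(iv, h3k4me1) > median_min
        or _per_base_median(iv, h3k4me3) > median_min
    ]
    report.record("median_h3k4_signal", n0, len(final))
    return (
        RegionSet(kind="enhancer", regions=final, cell_line=list_a.cell_line, grid=grid),
        report,
    )
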