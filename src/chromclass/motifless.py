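"""Motifless binding peaks and their overlap with HOT regions.

A peak of a TRF is motifless if it contains neither a previously known nor
a newly discovered sequence motif of that TRF (motifs of other TRFs are
allowed).  The per-cell-line motifless set is the union over TRFs.  Overlap
between motifless peaks and the HOT regions restricted to peak space is
assessed by block sampling within the whole-peak-set domain, with a
Gaussian fitted to the null overlap ratios and p-values computed in log
space (z-scores above 38 underflow double precision otherwise).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Annotation,
    Interval,
    PeakSet,
    RegionSet,
    intersect_intervals,
    normalize_intervals,
    subtract_intervals,
    total_bases,
)
from .hotlot import OverlapZ, block_overlap_z

# spec'd public names
block_sample_overlap_z = block_overlap_z


def motifless_peaks(
    peaksets: Mapping[str, PeakSet],
    known_motif_sites: Mapping[str, Sequence[Interval]],
    novel_motif_sites: Mapping[str, Sequence[Interval]],
) -> list[Interval]:
    """Union over TRFs of peaks containing no motif site of their own TRF."""
    out: list[Interval] = []
    for trf, ps in peaksets.items():
        sites = normalize_intervals(
            list(known_motif_sites.get(trf, [])) + list(novel_motif_sites.get(trf, []))
        )
        by_chrom: dict[str, list[Interval]] = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s)
        for p in ps.peaks:
            chrom_sites = by_chrom.get(p.chrom, [])
            if not any(p.overlaps(s) for s in chrom_sites):
                out.append(p)
    return normalize_intervals(out)


def hot_within_peaks(hot: RegionSet, all_peaks: Sequence[Interval]) -> RegionSet:
    """Clip HOT regions to the bases covered by the peak-set union."""
    inter = intersect_intervals(hot.regions, all_peaks)
    return RegionSet(kind="HOT_in_peaks", regions=inter, cell_line=hot.cell_line,
                     grid=hot.grid)


def intergenic_restrict(
    regions: Sequence[Interval] | RegionSet,
    annotation: Annotation,
    min_dist: int = 10_000,
) -> list[Interval]:
    """Keep the bases at least ``min_dist`` bp from every gene span
    (regions straddling the boundary are clipped at it)."""
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    ivs = regions.regions if isinstance(regions, RegionSet) else list(regions)
    forbidden = [
        Interval(g.chrom, max(0, g.start - min_dist), g.end + min_dist)
        for g in annotation.gene_spans()
    ]
    return subtract_intervals(ivs, forbidden)


def motifless_hot_table(
    peaksets_by_cell: Mapping[str, Mapping[str, PeakSet]],
    hot_by_cell: Mapping[str, RegionSet],
    known_motif_sites: Mapping[str, Sequence[Interval]],
    novel_motif_sites: Mapping[str, Sequence[Interval]],
    annotation: Annotation | None = None,
    intergenic: bool = False,
    n_samples: int = 10_000,
    block_length: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell-line overlap table of motifless peaks vs HOT-in-peaks.

    One row per cell line: peak bases, HOT bases, HOT-in-peak bases, motifless bases,
    intersection bases, overlap ratio and block-sampling z.  With
    ``intergenic=True`` every set is first restricted to bases >= 10 kb from
    any gene.
    """
    rows = []
    for ci, (cl, peaksets) in enumerate(sorted(peaksets_by_cell.items())):
        all_peaks = normalize_intervals(
            [p for ps in peaksets.values() for p in ps.peaks]
        )
        motifless = motifless_peaks(peaksets, known_motif_sites, novel_motif_sites)
        hot = hot_by_cell[cl]
        hot_regions = list(hot.regions)
        if intergenic:
            if annotation is None:
                raise ValueError("intergenic restriction requires an annotation")
            all_peaks = intergenic_restrict(all_peaks, annotation)
            motifless = intersect_intervals(motifless, all_peaks)
            hot_regions = intergenic_restrict(hot_regions, annotation)
        hot_in_peaks = intersect_intervals(hot_regions, all_peaks)
        inter = intersect_intervals(hot_in_peaks, motifless)
        res = block_overlap_z(
            hot_in_peaks,
            motifless,
            domain=all_peaks,
            n_samples=n_samples,
            block_length=block_length,
            seed=seed * 100 + ci,
        )
        rows.append(
            {
                "cell_line": cl,
                "peak_mbp": total_bases(all_peaks) / 1e6,
                "hot_mbp": total_bases(hot_regions) / 1e6,
                "hot_in_peak_mbp": total_bases(hot_in_peaks) / 1e6,
                "motifless_mbp": total_bases(motifless) / 1e6,
                "intersection_mbp": total_bases(inter) / 1e6,
                "overlap_ratio": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "z": res.z,
                "log10_p": res.log10_p(),
            }
        )
    return pd.DataFrame(rows)
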