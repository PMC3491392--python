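"""Association of distal regulatory modules (DRMs) with target transcripts.

DRM bins from all cell lines are merged into modules (100 bp gaps allowed);
modules and transcripts are filtered by signal-level and fold-change rules;
for each candidate (module, transcript, mark, assay) pair within 1 Mbp on
the same chromosome with enough matched cell lines, the Pearson correlation
between the module's mark signal and the transcript's expression across
cell lines is tested with the Fisher transformation and kept under a
Bonferroni-corrected p < 0.01 (family = all tested pairs of one
(mark, assay) combination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    Annotation,
    BinGrid,
    Interval,
    PeakSet,
    RegionSet,
    merge_intervals,
)

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "module_id", "transcript_id", "mark", "assay", "n", "r", "p", "p_bonf",
    "distance", "trfs",
]


@dataclass
class DRMModule:
    """A merged cross-cell-line DRM interval."""

    module_id: str
    interval: Interval
    bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def merge_drm_modules(
    drm_sets: Sequence[RegionSet], max_gap: int = 100
) -> list[DRMModule]:
    """Union of per-cell-line DRM bins merged with ``max_gap`` bp gaps."""
    if not drm_sets:
        raise ValueError("need at least one cell line of DRMs")
    ivs = [iv for rs in drm_sets for iv in rs.regions]
    merged = merge_intervals(ivs, max_gap=max_gap)
    grid = next((rs.grid for rs in drm_sets if rs.grid is not None), None)
    out = []
    for k, iv in enumerate(merged):
        bins = (
            grid.bins_in_range(iv.chrom, iv.start, iv.end)
            if grid is not None
            else np.empty(0, dtype=np.int64)
        )
        out.append(DRMModule(module_id=f"M{k:06d}", interval=iv, bins=bins))
    return out


def module_mark_summaries(
    modules: Sequence[DRMModule],
    mark_tracks: Mapping[str, Mapping[str, "SignalTrack"]],
    stat: str = "mean",
) -> dict[str, pd.DataFrame]:
    """Per mark: DataFrame (module x cell line) of summary signal.

    ``mark_tracks`` maps cell line -> mark -> SignalTrack; the summary is the
    mean (or max) of the track over the module's member bins.
    """
    cells = list(mark_tracks)
    marks = sorted({m for cl in cells for m in mark_tracks[cl]})
    fn = np.mean if stat == "mean" else np.max
    out = {}
    for mark in marks:
        data = np.full((len(modules), len(cells)), np.nan)
        for j, cl in enumerate(cells):
            track = mark_tracks[cl].get(mark)
            if track is None:
                continue
            for i, m in enumerate(modules):
                data[i, j] = float(fn(track.values[m.bins]))
        out[mark] = pd.DataFrame(
            data, index=[m.module_id for m in modules], columns=cells
        )
    return out


def _passes_level_fold(values: np.ndarray, min_level: float, min_fold: float) -> bool:
    """max >= min_level AND fold(max/min) >= min_fold; a zero minimum counts
    as infinite fold.  NaNs (missing cell lines) are ignored."""
    v = values[~np.isnan(values)]
    if len(v) < 2:
        return False
    vmax, vmin = float(v.max()), float(v.min())
    if vmax < min_level:
        return False
    if vmin == 0:
        return True
    return vmax / vmin >= min_fold


def filter_transcripts(
    expression: pd.DataFrame,
    min_level: float = 2.0,
    min_fold: float = 2.0,
    per_assay: bool = False,
):
    """Transcripts with >= min_level somewhere and >= min_fold variation.

    With ``per_assay=True`` returns {assay: set of ids}; otherwise the set of
    transcripts eligible in at least one assay.
    """
    assays = sorted(set(expression.columns.get_level_values("assay")))
    result: dict[str, set[str]] = {}
    for assay in assays:
        sub = expression.xs(assay, axis=1, level="assay")
        vals = sub.to_numpy(dtype=float)
        ok = [
            _passes_level_fold(vals[i], min_level, min_fold)
            for i in range(vals.shape[0])
        ]
        result[assay] = set(expression.index[np.array(ok, dtype=bool)])
    if per_assay:
        return result
    return set().union(*result.values()) if result else set()


def filter_module_marks(
    summaries: Mapping[str, pd.DataFrame],
    min_level: float = 2.0,
    min_fold: float = 2.0,
) -> set[tuple[str, str]]:
    """Eligible (module_id, mark) pairs by the same level/fold rule."""
    out = set()
    for mark, df in summaries.items():
        vals = df.to_numpy(dtype=float)
        for i, mid in enumerate(df.index):
            if _passes_level_fold(vals[i], min_level, min_fold):
                out.add((mid, mark))
    return out


def candidate_pairs(
    modules: Sequence[DRMModule],
    annotation: Annotation,
    summaries: Mapping[str, pd.DataFrame],
    expression: pd.DataFrame,
    eligible_transcripts: Mapping[str, set[str]] | set[str] | None = None,
    eligible_module_marks: set[tuple[str, str]] | None = None,
    max_dist: int = 1_000_000,
    min_matched_cells: int = 7,
) -> list[dict]:
    """Candidate (module, transcript, mark, assay) records.

    Same chromosome, TSS within ``max_dist`` of the nearest module edge, and
    at least ``min_matched_cells`` cell lines carrying both the mark summary
    and the expression value.
    """
    tss = sorted(
        ((t.chrom, t.tss, t.transcript_id) for t in annotation.transcripts),
        key=lambda x: (x[0], x[1]),
    )
    assays = sorted(set(expression.columns.get_level_values("assay")))
    present: dict[str, dict[str, frozenset[str]]] = {}
    for a in assays:
        sub = expression.xs(a, axis=1, level="assay")
        notna = sub.notna()
        present[a] = {
            tid: frozenset(sub.columns[notna.loc[tid].to_numpy()])
            for tid in sub.index
        }
    mark_cells_by_module: dict[str, dict[str, frozenset[str]]] = {}
    for mark, df in summaries.items():
        notna = df.notna()
        mark_cells_by_module[mark] = {
            mid: frozenset(df.columns[notna.loc[mid].to_numpy()]) for mid in df.index
        }
    out: list[dict] = []
    for m in modules:
        iv = m.interval
        for chrom, pos, tid in tss:
            if chrom != iv.chrom:
                continue
            if iv.start <= pos < iv.end:
                d = 0
            else:
                d = min(abs(pos - iv.start), abs(pos - (iv.end - 1)))
            if d > max_dist:
                continue
            for mark in summaries:
                if eligible_module_marks is not None and (m.module_id, mark) not in eligible_module_marks:
                    continue
                mark_cells = mark_cells_by_module[mark][m.module_id]
                for assay in assays:
                    if eligible_transcripts is not None:
                        ok = (
                            eligible_transcripts.get(assay, set())
                            if isinstance(eligible_transcripts, dict)
                            else eligible_transcripts
                        )
                        if tid not in ok:
                            continue
                    matched = sorted(mark_cells & present[assay][tid])
                    if len(matched) < min_matched_cells:
                        continue
                    out.append(
                        {
                            "module_id": m.module_id,
                            "transcript_id": tid,
                            "mark": mark,
                            "assay": assay,
                            "cells": matched,
                            "distance": d,
                        }
                    )
    return out


def correlate_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Pearson r and two-sided Fisher-transform p; None if undefined.

    z = atanh(r) * sqrt(n - 3); p is the two-sided standard-normal tail.
    Requires n >= 4 and non-degenerate variance in both vectors.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        logger.info("pair skipped: fewer than 4 matched values")
        return None
    if np.std(x) == 0 or np.std(y) == 0:
        logger.info("pair skipped: zero variance")
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r, min(p, 1.0)


def correlate_candidates(
    candidates: Sequence[dict],
    summaries: Mapping[str, pd.DataFrame],
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Compute (r, p) for every candidate; returns the unselected pair table."""
    rows = []
    assays = sorted(set(expression.columns.get_level_values("assay")))
    expr_by_assay = {a: expression.xs(a, axis=1, level="assay") for a in assays}
    for c in candidates:
        x = summaries[c["mark"]].loc[c["module_id"], c["cells"]].to_numpy(float)
        y = expr_by_assay[c["assay"]].loc[c["transcript_id"], c["cells"]].to_numpy(float)
        res = correlate_pair(x, y)
        if res is None:
            continue
        r, p = res
        rows.append(
            {
                "module_id": c["module_id"],
                "transcript_id": c["transcript_id"],
                "mark": c["mark"],
                "assay": c["assay"],
                "n": len(c["cells"]),
                "r": r,
                "p": p,
                "distance": c["distance"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["module_id", "transcript_id", "mark", "assay", "n", "r", "p", "distance"],
    )


def select_pairs(
    tested: pd.DataFrame, alpha: float = 0.01, family: str = "per_combination"
) -> pd.DataFrame:
    """Bonferroni selection: keep pairs with p * m < alpha.

    ``family='per_combination'`` corrects within each (mark, assay)
    combination; ``'global'`` uses all tested pairs as one family.
    """
    if tested.empty:
        out = tested.copy()
        out["p_bonf"] = pd.Series(dtype=float)
        return out
    out = tested.copy()
    if family == "per_combination":
        m = out.groupby(["mark", "assay"])["p"].transform("size")
    elif family == "global":
        m = float(len(out))
    else:
        raise ValueError(f"unknown family {family!r}")
    out["p_bonf"] = np.minimum(out["p"] * m, 1.0)
    kept = out[(out["p"] * m) < alpha].reset_index(drop=True)
    return kept


def associate_trfs(
    pairs: pd.DataFrame,
    modules: Sequence[DRMModule],
    peaksets: Mapping[str, Mapping[str, PeakSet]],
    summaries: Mapping[str, pd.DataFrame],
    min_mark_signal: float = 2.0,
) -> pd.DataFrame:
    """Attach to each pair the TRFs with a peak at the module in a cell line
    where the pair's mark summary is >= min_mark_signal."""
    by_id = {m.module_id: m for m in modules}
    trf_lists = []
    for _, row in pairs.iterrows():
        m = by_id[row["module_id"]]
        df = summaries[row["mark"]]
        found: set[str] = set()
        for cl in df.columns:
            v = df.loc[m.module_id, cl]
            if np.isnan(v) or v < min_mark_signal:
                continue
            for trf, ps in peaksets.get(cl, {}).items():
                if trf in found:
                    continue
                if any(p.overlaps(m.interval) for p in ps.peaks):
                    found.add(trf)
        trf_lists.append(",".join(sorted(found)))
    out = pairs.copy()
    out["trfs"] = trf_lists
    return out


def ctcf_interposition(
    pairs: pd.DataFrame,
    modules: Sequence[DRMModule],
    annotation: Annotation,
    ctcf_peaks: Sequence[Interval],
) -> float:
    """Fraction of pairs with >= 1 CTCF peak strictly between the nearest
    module edge and the target TSS (open interval)."""
    if pairs.empty:
        return float("nan")
    by_id = {m.module_id: m for m in modules}
    tss = {t.transcript_id: (t.chrom, t.tss) for t in annotation.transcripts}
    peaks = sorted(ctcf_peaks, key=lambda iv: (iv.chrom, iv.start))
    n_with = 0
    for _, row in pairs.iterrows():
        iv = by_id[row["module_id"]].interval
        chrom, pos = tss[row["transcript_id"]]
        if chrom != iv.chrom:
            continue
        if pos >= iv.end:
            lo, hi = iv.end, pos
        elif pos < iv.start:
            lo, hi = pos + 1, iv.start
        else:
            continue  # TSS inside the module: empty between-interval
        if lo >= hi:
            continue
        if any(p.chrom == chrom and p.start < hi and p.end > lo for p in peaks):
            n_with += 1
    return n_with / len(pairs)


def pair_summaries(pairs: pd.DataFrame, max_dist: int = 1_000_000) -> dict:
    """Distance histogram (fixed 100-kb bins) per assay and degree counts."""
    edges = np.arange(0, max_dist + 100_000, 100_000)
    out: dict = {"distance_hist": {}, "pairs_per_mark": {}, }
    for assay, sub in pairs.groupby("assay"):
        hist, _ = np.histogram(sub["distance"], bins=edges)
        out["distance_hist"][assay] = hist.tolist()
    out["transcripts_per_module"] = (
        pairs.groupby("module_id")["transcript_id"].nunique().to_dict()
    )
    out["modules_per_transcript"] = (
        pairs.groupby("transcript_id")["module_id"].nunique().to_dict()
    )
    out["pairs_per_mark"] = pairs.groupby("mark").size().to_dict()
    return out
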