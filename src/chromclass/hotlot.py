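"""Region-specific TRF co-occurrence degree and HOT/LOT region calling.

Per TRF, replicate binding tracks are averaged and discretized into five
levels (0 for zero signal; the nonzero values split into quartiles, coded
1-4 from bottom to top).  Each TRF receives a weight from its global
co-occurrence with all other TRFs: the least co-associating TRF gets weight
1, the most co-associating gets 1/n, linear in between.  A bin's degree of
region-specific co-occurrence is the weighted sum of its levels over TRFs;
HOT regions are the top 1% of bins by degree, LOT regions the bottom 1% of
the bins with nonzero degree.

The global co-occurrence z-score matrix can be supplied or estimated here
with a fixed-length block bootstrap: one peak set's base mass is re-placed
as uniform blocks within the domain and the base-overlap ratio with the
other set is recorded; z is the observed ratio standardized by the null
sample moments.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    BinGrid,
    Interval,
    PeakSet,
    RegionSet,
    SignalTrack,
    intersect_intervals,
    normalize_intervals,
    total_bases,
)


@dataclass
class DiscretizedTrack:
    """Per-bin level in {0..4} for one TRF, with the quartile thresholds."""

    levels: np.ndarray  # int8 per bin
    thresholds: tuple[float, float, float] | None  # None when all-zero


@dataclass
class TRFWeights:
    trfs: list[str]
    raw: np.ndarray  # mean off-diagonal z per TRF
    weights: np.ndarray  # in [1/n, 1]


@dataclass
class DegreeTrack:
    grid: BinGrid
    degrees: np.ndarray
    cell_line: str = ""


def average_trf_tracks(
    tracks_by_trf: Mapping[str, Sequence[SignalTrack]]
) -> dict[str, SignalTrack]:
    """Arithmetic mean of replicate tracks per TRF."""
    out = {}
    for trf, tracks in tracks_by_trf.items():
        if not tracks:
            raise ValueError(f"no tracks for TRF {trf}")
        vals = np.mean([t.values for t in tracks], axis=0)
        out[trf] = SignalTrack(
            tracks[0].grid, vals, assay=f"{trf} mean", cell_line=tracks[0].cell_line
        )
    return out


def _nearest_rank(sorted_vals: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: smallest value with >= p of mass at or below."""
    n = len(sorted_vals)
    k = max(1, int(np.ceil(p * n)))
    return float(sorted_vals[k - 1])


def discretize_track(track: SignalTrack | np.ndarray) -> DiscretizedTrack:
    """Five-level discretization: 0 for zeros, nonzero quartiles coded 1-4.

    Thresholds are the nearest-rank 25/50/75 percentiles of the nonzero
    values; values equal to a threshold fall in the lower level.
    """
    values = track.values if isinstance(track, SignalTrack) else np.asarray(track, float)
    levels = np.zeros(len(values), dtype=np.int8)
    nz = values[values > 0]
    if len(nz) == 0:
        return DiscretizedTrack(levels, None)
    s = np.sort(nz)
    t = tuple(_nearest_rank(s, p) for p in (0.25, 0.5, 0.75))
    mask = values > 0
    lv = np.ones(int(mask.sum()), dtype=np.int8)
    v = values[mask]
    for thr in t:
        lv += (v > thr).astype(np.int8)
    levels[mask] = lv
    return DiscretizedTrack(levels, t)  # type: ignore[arg-type]


def trf_weights(coocc: pd.DataFrame) -> TRFWeights:
    """Linear map of mean off-diagonal co-occurrence z to weights in [1/n, 1].

    The TRF with the lowest raw score (least globally co-associating) gets
    weight 1; the highest gets 1/n.
    """
    if coocc.shape[0] != coocc.shape[1] or list(coocc.index) != list(coocc.columns):
        raise ValueError("co-occurrence matrix must be square with matching labels")
    trfs = list(coocc.index)
    n = len(trfs)
    M = coocc.to_numpy(dtype=float).copy()
    np.fill_diagonal(M, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.nanmean(M, axis=1)
    if n == 1 or np.isnan(raw).all():
        return TRFWeights(trfs, raw, np.ones(n))
    rmin, rmax = np.nanmin(raw), np.nanmax(raw)
    if rmax == rmin:
        warnings.warn("all TRF raw co-occurrence scores equal; uniform weights")
        return TRFWeights(trfs, raw, np.ones(n))
    w = 1.0 + (raw - rmin) / (rmax - rmin) * (1.0 / n - 1.0)
    return TRFWeights(trfs, raw, w)


def cooccurrence_degree(
    levels_by_trf: Mapping[str, DiscretizedTrack] | Mapping[str, np.ndarray],
    weights: TRFWeights,
    grid: BinGrid,
    cell_line: str = "",
) -> DegreeTrack:
    """Degree D_b = sum_t w_t * level_{t,b}."""
    D = np.zeros(grid.n_bins)
    for trf, w in zip(weights.trfs, weights.weights):
        lv = levels_by_trf[trf]
        arr = lv.levels if isinstance(lv, DiscretizedTrack) else np.asarray(lv)
        if len(arr) != grid.n_bins:
            raise ValueError(f"level vector for {trf} has wrong length")
        D += w * arr
    return DegreeTrack(grid, D, cell_line=cell_line)


def call_hot_lot(
    degrees: DegreeTrack, pct: float = 0.01, cell_line: str = ""
) -> tuple[RegionSet, RegionSet]:
    """Top pct of all bins by degree (HOT) and bottom pct of nonzero-degree
    bins (LOT); ties broken toward the lowest bin index.

    A bin already selected as HOT is never also LOT (relevant only under
    massive degree ties).
    """
    if not (0 < pct < 0.5):
        raise ValueError("pct must be in (0, 0.5)")
    D = degrees.degrees
    N = len(D)
    cl = cell_line or degrees.cell_line
    k_hot = int(np.floor(pct * N))
    order_hot = np.lexsort((np.arange(N), -D))
    hot_idx = np.sort(order_hot[:k_hot])
    nz = np.flatnonzero(D > 0)
    k_lot = int(np.floor(pct * len(nz)))
    hot_set = set(int(i) for i in hot_idx)
    nz_eligible = nz[[int(i) not in hot_set for i in nz]]
    order_lot = np.lexsort((nz_eligible, D[nz_eligible]))
    lot_idx = np.sort(nz_eligible[order_lot[:k_lot]])
    hot = RegionSet.from_bins(degrees.grid, hot_idx, kind="HOT", cell_line=cl,
                              scores=D[hot_idx])
    lot = RegionSet.from_bins(degrees.grid, lot_idx, kind="LOT", cell_line=cl,
                              scores=D[lot_idx])
    return hot, lot


def region_cooccurrence_degrees(
    trf_tracks: Mapping[str, Sequence[SignalTrack]],
    coocc: pd.DataFrame,
    grid: BinGrid,
    cell_line: str = "",
) -> tuple[DegreeTrack, TRFWeights, dict[str, DiscretizedTrack]]:
    """Average replicates, discretize, weight and sum: the full degree stage."""
    mean_tracks = average_trf_tracks(trf_tracks)
    weights = trf_weights(coocc.loc[list(mean_tracks), list(mean_tracks)])
    disc = {trf: discretize_track(t) for trf, t in mean_tracks.items()}
    deg = cooccurrence_degree(disc, weights, grid, cell_line=cell_line)
    return deg, weights, disc


# ---------------------------------------------------------------------------
# Block-bootstrap overlap machinery


def log10_normal_sf(z: float) -> float:
    """log10 of the one-sided standard-normal upper tail, computed in log
    space so it survives z far beyond the double-precision underflow point
    (the tail at z = 38 is ~5e-317; beyond that norm.sf returns 0)."""
    from scipy.stats import norm

    return float(norm.logsf(z) / np.log(10.0))


@dataclass
class OverlapZ:
    """Observed base-overlap ratio against a Gaussian fitted to the block null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_samples: int
    block_length: int
    seed: int

    def log10_p(self) -> float:
        """One-sided upper-tail Gaussian p-value of z, in log10."""
        return log10_normal_sf(self.z)

    def p_value(self) -> float:
        return float(10.0 ** self.log10_p())


class _Domain:
    """A union of intervals concatenated onto one coordinate line.

    Interval order is preserved as given, so results do not depend on
    chromosome naming.
    """

    def __init__(self, intervals: Sequence[Interval]):
        ivs = list(intervals)
        if not ivs:
            raise ValueError("empty domain")
        self.intervals = ivs
        self.offsets = np.concatenate([[0], np.cumsum([len(iv) for iv in ivs])])
        self.length = int(self.offsets[-1])

    def occupancy(self, intervals: Sequence[Interval]) -> np.ndarray:
        """0/1 base mask of the given set within domain coordinates."""
        by_chrom: dict[str, list[Interval]] = {}
        for iv in normalize_intervals(intervals):
            by_chrom.setdefault(iv.chrom, []).append(iv)
        starts = {c: [iv.start for iv in l] for c, l in by_chrom.items()}
        occ = np.zeros(self.length, dtype=np.uint8)
        for d, off in zip(self.intervals, self.offsets[:-1]):
            lst = by_chrom.get(d.chrom)
            if not lst:
                continue
            i = bisect_right(starts[d.chrom], d.start)
            if i > 0 and lst[i - 1].end > d.start:
                i -= 1
            while i < len(lst) and lst[i].start < d.end:
                s = max(lst[i].start, d.start)
                e = min(lst[i].end, d.end)
                if s < e:
                    occ[off + (s - d.start) : off + (e - d.start)] = 1
                i += 1
        return occ


def _null_overlap_ratios(
    cumB: np.ndarray,
    domain_length: int,
    a_mass: int,
    block_length: int,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of |A* ∩ B| / |A| for block-resampled A*."""
    block_length = min(block_length, domain_length)
    n_full, rem = divmod(a_mass, block_length)
    lens = [block_length] * n_full + ([rem] if rem else [])
    ratios = np.zeros(n_samples)
    for L in set(lens):
        count = lens.count(L)
        starts = rng.integers(0, domain_length - L + 1, size=(n_samples, count))
        ratios += (cumB[starts + L] - cumB[starts]).sum(axis=1)
    return ratios / a_mass


def block_overlap_z(
    setA: Sequence[Interval],
    setB: Sequence[Interval],
    domain: Sequence[Interval],
    n_samples: int = 10_000,
    block_length: int | None = None,
    seed: int = 0,
) -> "OverlapZ":
    """Observed |A ∩ B| / |A| within the domain against a block-bootstrap null.

    A's base mass is re-placed as fixed-length blocks uniformly in the
    domain, holding B fixed; the null ratios are summarized by a fitted
    Gaussian (sample mean and sd) and the observed ratio standardized.
    """
    dom = _Domain(domain)
    a_dom = intersect_intervals(setA, domain)
    a_mass = total_bases(a_dom)
    if a_mass == 0:
        raise ValueError("set A has no bases inside the domain")
    if total_bases(a_dom) < total_bases(normalize_intervals(setA)):
        warnings.warn("set A extends outside the domain; clipped")
    occB = dom.occupancy(setB)
    cumB = np.concatenate([[0], np.cumsum(occB, dtype=np.int64)])
    obs = total_bases(intersect_intervals(a_dom, setB)) / a_mass
    if block_length is None:
        mean_len = a_mass / max(1, len(normalize_intervals(a_dom)))
        block_length = max(1, int(round(10 * mean_len)))
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    ratios = _null_overlap_ratios(cumB, dom.length, a_mass, block_length, n_samples, rng)
    mu = float(ratios.mean())
    sigma = float(ratios.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate null: zero variance in block-sample overlaps")
    return OverlapZ(
        observed=obs, null_mean=mu, null_sd=sigma, z=(obs - mu) / sigma,
        n_samples=n_samples, block_length=block_length, seed=seed,
    )


def estimate_cooccurrence_z(
    peaksets: Sequence[PeakSet],
    domain: Sequence[Interval],
    block_length: int | None = None,
    n_samples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise global co-occurrence z-score matrix of TRF peak sets.

    For each pair, the first set is block-resampled within the domain and
    its base-overlap ratio with the second recorded; z standardizes the
    observed ratio.  Degenerate nulls yield NaN with a warning.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets")
    trfs = [ps.trf for ps in peaksets]
    n = len(trfs)
    Z = np.full((n, n), np.nan)
    dom = _Domain(domain)
    rng = np.random.default_rng(seed)
    for j in range(n):
        occB = dom.occupancy(peaksets[j].peaks)
        cumB = np.concatenate([[0], np.cumsum(occB, dtype=np.int64)])
        for i in range(j + 1):
            a_dom = intersect_intervals(peaksets[i].peaks, domain)
            a_mass = total_bases(a_dom)
            if a_mass == 0:
                warnings.warn(f"{trfs[i]}: no peak bases in domain; z undefined")
                continue
            obs = total_bases(intersect_intervals(a_dom, peaksets[j].peaks)) / a_mass
            bl = block_length
            if bl is None:
                bl = max(1, int(round(10 * a_mass / max(1, len(a_dom)))))
            ratios = _null_overlap_ratios(
                cumB, dom.length, a_mass, bl, n_samples, rng
            )
            sd = ratios.std(ddof=1)
            if sd == 0:
                warnings.warn(f"degenerate null for pair ({trfs[i]}, {trfs[j]})")
                continue
            Z[i, j] = Z[j, i] = (obs - ratios.mean()) / sd
    return pd.DataFrame(Z, index=trfs, columns=trfs)
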