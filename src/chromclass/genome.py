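"""Genome coordinate model, fixed-width binning and interval algebra.

All coordinates are 0-based half-open ``[start, end)``.  One-based formats
(GTF) are converted at the I/O boundary.  A :class:`BinGrid` partitions every
chromosome into fixed-width bins (the last bin of a chromosome may be
shorter); bins are addressed by a single global integer index so that signal
tracks are plain NumPy vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "BinGrid",
    "Interval",
    "SignalTrack",
    "PeakSet",
    "Transcript",
    "Annotation",
    "make_bins",
    "average_signal",
    "bins_overlapping",
    "distance_to_features",
    "merge_intervals",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and their lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        if len(names) != len(lengths):
            raise InvalidInputError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise InvalidInputError("chromosome names must be unique")
        if any(l < 1 for l in lengths):
            raise InvalidInputError("chromosome lengths must be >= 1")
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True)
class Interval:
    """A genomic interval, optionally stranded and valued."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    value: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidInputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise InvalidInputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class BinGrid:
    """Fixed-width tiling of a genome; the universal bin coordinate system.

    Bins are numbered globally, chromosome by chromosome in genome order.
    Every chromosome is tiled with ``ceil(length / width)`` bins; all bins
    have length ``width`` except possibly the trailing bin of a chromosome,
    which is kept (not dropped) and can be identified via
    :meth:`is_partial_bin`.
    """

    def __init__(self, genome: GenomeSpec, width: int = 100):
        if width < 1:
            raise InvalidInputError("bin width must be >= 1")
        if not genome.chrom_names:
            raise InvalidInputError("empty genome")
        self.genome = genome
        self.width = int(width)
        nbins = np.array(
            [-(-l // width) for l in genome.chrom_lengths], dtype=np.int64
        )
        self._nbins = nbins
        self._offsets = np.concatenate([[0], np.cumsum(nbins)])
        self._chrom_index = {c: i for i, c in enumerate(genome.chrom_names)}

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    def __len__(self) -> int:
        return self.n_bins

    def chrom_offset(self, chrom: str) -> int:
        return int(self._offsets[self._chrom_index[chrom]])

    def chrom_nbins(self, chrom: str) -> int:
        return int(self._nbins[self._chrom_index[chrom]])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base ``pos``."""
        ci = self._chrom_index[chrom]
        if not (0 <= pos < self.genome.chrom_lengths[ci]):
            raise InvalidInputError(f"position {pos} outside {chrom}")
        return int(self._offsets[ci] + pos // self.width)

    def bin_bounds(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin index."""
        if not (0 <= index < self.n_bins):
            raise InvalidInputError(f"bin index {index} out of range")
        ci = int(np.searchsorted(self._offsets, index, side="right") - 1)
        local = index - int(self._offsets[ci])
        start = local * self.width
        end = min(start + self.width, self.genome.chrom_lengths[ci])
        return self.genome.chrom_names[ci], start, end

    def bin_interval(self, index: int) -> Interval:
        chrom, start, end = self.bin_bounds(index)
        return Interval(chrom, start, end)

    def bin_length(self, index: int) -> int:
        _, s, e = self.bin_bounds(index)
        return e - s

    def is_partial_bin(self, index: int) -> bool:
        return self.bin_length(index) < self.width

    def bin_lengths(self) -> np.ndarray:
        """Vector of true bin lengths (trailing bins may be short)."""
        out = np.full(self.n_bins, self.width, dtype=np.int64)
        for ci, l in enumerate(self.genome.chrom_lengths):
            rem = l % self.width
            if rem:
                out[int(self._offsets[ci + 1]) - 1] = rem
        return out

    def bins_in_range(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of all bins sharing >= 1 base with [start, end)."""
        ci = self._chrom_index[chrom]
        length = self.genome.chrom_lengths[ci]
        if not (0 <= start < end <= length):
            raise InvalidInputError(
                f"interval {chrom}:{start}-{end} outside chromosome (len {length})"
            )
        off = int(self._offsets[ci])
        first = start // self.width
        last = (end - 1) // self.width
        return np.arange(off + first, off + last + 1, dtype=np.int64)

    def iter_bins(self) -> Iterator[tuple[int, str, int, int]]:
        for i in range(self.n_bins):
            chrom, s, e = self.bin_bounds(i)
            yield i, chrom, s, e

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinGrid)
            and other.genome == self.genome
            and other.width == self.width
        )


@dataclass
class SignalTrack:
    """Per-bin mean signal for one (assay, cell line); dense, zeros for no data."""

    grid: BinGrid
    values: np.ndarray
    assay: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise InvalidInputError(
                f"track length {self.values.shape} != bin count {self.grid.n_bins}"
            )
        if np.isnan(self.values).any():
            raise InvalidInputError("signal track contains NaN")

    def __len__(self) -> int:
        return self.grid.n_bins


@dataclass
class PeakSet:
    """Peak calls of one TRF in one cell line, sorted and non-overlapping."""

    trf: str
    cell_line: str
    peaks: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = normalize_intervals(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def total_bases(self) -> int:
        return sum(len(p) for p in self.peaks)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise InvalidInputError("transcript without exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise InvalidInputError("overlapping exons within a transcript")
        object.__setattr__(self, "exons", exons)
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"transcript strand must be +/-, got {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site: first base transcribed (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, strand=self.strand)


class Annotation:
    """A set of transcripts grouped into genes."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts = list(transcripts)
        self._by_gene: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_gene.setdefault(t.gene_id, []).append(t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._by_gene)

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return list(self._by_gene[gene_id])

    def gene_spans(self) -> list[Interval]:
        """Union span of each gene's transcripts (one interval per gene)."""
        spans = []
        for gid, ts in self._by_gene.items():
            chrom = ts[0].chrom
            spans.append(
                Interval(chrom, min(t.start for t in ts), max(t.end for t in ts), name=gid)
            )
        return sorted(spans, key=lambda iv: (iv.chrom, iv.start))

    def tss_positions(self) -> list[tuple[str, int, str, str]]:
        """(chrom, tss, strand, transcript_id) for every transcript."""
        return [(t.chrom, t.tss, t.strand, t.transcript_id) for t in self.transcripts]

    def exon_intervals(self) -> list[Interval]:
        out = []
        for t in self.transcripts:
            for s, e in t.exons:
                out.append(Interval(t.chrom, s, e, strand=t.strand))
        return sorted(out, key=lambda iv: (iv.chrom, iv.start))


# ---------------------------------------------------------------------------
# Interval algebra


def normalize_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort by (chrom, start) and merge overlapping intervals (gap 0 kept)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = replace(prev, end=iv.end)
        else:
            out.append(iv)
    return out


def make_bins(genome: GenomeSpec, width: int = 100) -> BinGrid:
    """Partition every chromosome into fixed-width bins."""
    return BinGrid(genome, width)


def average_signal(
    intervals: Iterable[Interval],
    grid: BinGrid,
    *,
    assay: str = "",
    cell_line: str = "",
    uncovered_as_zero: bool = True,
) -> SignalTrack:
    """Coverage-weighted mean of interval values over each bin's bases.

    Each base covered by an interval takes that interval's value (overlapping
    input intervals contribute additively, as stacked coverage).  With
    ``uncovered_as_zero`` (the default) bases covered by no interval
    contribute 0 to the mean, i.e. the bin value is
    ``sum(value_i * covered_bases_i) / bin_length``; otherwise the mean is
    taken over covered bases only (bins with no coverage stay 0).
    """
    total = np.zeros(grid.n_bins)
    covered = np.zeros(grid.n_bins)
    width = grid.width
    for iv in intervals:
        if iv.chrom not in grid.genome:
            raise InvalidInputError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > grid.genome.length(iv.chrom):
            raise InvalidInputError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome"
            )
        value = 0.0 if iv.value is None else float(iv.value)
        idx = grid.bins_in_range(iv.chrom, iv.start, iv.end)
        if len(idx) == 1:
            ov = iv.end - iv.start
            total[idx[0]] += value * ov
            covered[idx[0]] += ov
            continue
        # bin boundaries within the interval, in chromosome coordinates
        off = grid.chrom_offset(iv.chrom)
        starts = (idx - off) * width
        ends = starts + width
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        np.add.at(total, idx, value * ov)
        np.add.at(covered, idx, ov)
    lengths = grid.bin_lengths().astype(float)
    if uncovered_as_zero:
        values = total / lengths
    else:
        values = np.divide(total, covered, out=np.zeros_like(total), where=covered > 0)
    return SignalTrack(grid, values, assay=assay, cell_line=cell_line)


def bins_overlapping(
    peaks: PeakSet | Iterable[Interval], grid: BinGrid
) -> np.ndarray:
    """Sorted global indices of bins sharing >= 1 base with >= 1 interval."""
    ivs = peaks.peaks if isinstance(peaks, PeakSet) else peaks
    chunks = [grid.bins_in_range(iv.chrom, iv.start, iv.end) for iv in ivs]
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Bases between two intervals on one chromosome; 0 if they overlap or abut."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end, 0)


def distance_to_features(
    queries: Iterable[Interval], anchors: Sequence[Interval]
) -> np.ndarray:
    """Minimal edge-to-edge distance in bp from each query to any anchor.

    Overlapping or abutting (end == start) pairs have distance 0.  Queries on
    a chromosome with no anchors get ``inf``.
    """
    anchors = list(anchors)
    if not anchors:
        raise InvalidInputError("empty anchor set")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {a.chrom for a in anchors}:
        ch = sorted((a for a in anchors if a.chrom == chrom), key=lambda iv: iv.start)
        starts = np.array([a.start for a in ch], dtype=np.int64)
        ends = np.array([a.end for a in ch], dtype=np.int64)
        # running max of ends makes the left-neighbour scan O(log n)
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    out = []
    for q in queries:
        if q.chrom not in by_chrom:
            out.append(np.inf)
            continue
        starts, maxends = by_chrom[q.chrom]
        i = int(np.searchsorted(starts, q.end, side="left"))
        best = np.inf
        if i < len(starts):
            best = min(best, starts[i] - q.end)
        if i > 0:
            gap_left = q.start - maxends[i - 1]
            best = min(best, max(gap_left, 0))
            if gap_left <= 0:
                best = 0.0
        out.append(max(float(best), 0.0))
    return np.array(out)


def merge_intervals(intervals: Iterable[Interval], max_gap: int = 0) -> list[Interval]:
    """Merge intervals whose gap is <= ``max_gap`` bases.

    Output is sorted with pairwise gaps strictly greater than ``max_gap``;
    ``max_gap=0`` merges overlapping and abutting intervals only.
    """
    if max_gap < 0:
        raise InvalidInputError("max_gap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[Interval] = []
    for iv in ivs:
        if (
            out
            and out[-1].chrom == iv.chrom
            and iv.start - out[-1].end <= max_gap
        ):
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = Interval(prev.chrom, prev.start, iv.end)
        else:
            out.append(Interval(iv.chrom, iv.start, iv.end))
    return out


def intersect_intervals(
    a: Iterable[Interval], b: Iterable[Interval]
) -> list[Interval]:
    """Base-level intersection of two interval sets (both normalized first)."""
    a = normalize_intervals(a)
    b = normalize_intervals(b)
    out: list[Interval] = []
    i = j = 0
    # merge-scan over chromosome-sorted lists
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        s = max(x.start, y.start)
        e = min(x.end, y.end)
        if s < e:
            out.append(Interval(x.chrom, s, e))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(
    a: Iterable[Interval], b: Iterable[Interval]
) -> list[Interval]:
    """Bases of ``a`` not covered by ``b``."""
    a = normalize_intervals(a)
    b = normalize_intervals(b)
    out: list[Interval] = []
    j = 0
    for x in a:
        cur = x.start
        while j < len(b) and (b[j].chrom < x.chrom or (b[j].chrom == x.chrom and b[j].end <= x.start)):
            j += 1
        k = j
        while k < len(b) and b[k].chrom == x.chrom and b[k].start < x.end:
            if b[k].start > cur:
                out.append(Interval(x.chrom, cur, b[k].start))
            cur = max(cur, b[k].end)
            k += 1
        if cur < x.end:
            out.append(Interval(x.chrom, cur, x.end))
    return out


def total_bases(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in normalize_intervals(intervals))


@dataclass
class RegionSet:
    """Called regions of one region type (BAR, BIR, PRM, DRM, HOT, LOT, ...).

    Holds both the merged intervals and, when the set was called on a grid,
    the underlying bin indices.
    """

    kind: str
    regions: list[Interval] = field(default_factory=list)
    cell_line: str = ""
    grid: BinGrid | None = None
    bin_indices: np.ndarray | None = None
    scores: np.ndarray | None = None  # aligned with bin_indices

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda iv: (iv.chrom, iv.start))
        if self.bin_indices is not None:
            self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)

    @classmethod
    def from_bins(
        cls,
        grid: BinGrid,
        indices: np.ndarray,
        kind: str,
        cell_line: str = "",
        max_gap: int = 0,
        scores: np.ndarray | None = None,
    ) -> "RegionSet":
        indices = np.unique(np.asarray(indices, dtype=np.int64))
        ivs = [grid.bin_interval(int(i)) for i in indices]
        merged = merge_intervals(ivs, max_gap=max_gap)
        if scores is not None:
            scores = np.asarray(scores, dtype=float)
        return cls(
            kind=kind,
            regions=merged,
            cell_line=cell_line,
            grid=grid,
            bin_indices=indices,
            scores=scores,
        )

    def __len__(self) -> int:
        return len(self.regions)

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.regions)

    def bin_index_set(self) -> set[int]:
        if self.bin_indices is None:
            raise InvalidInputError(f"{self.kind} region set carries no bin indices")
        return set(int(i) for i in self.bin_indices)
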