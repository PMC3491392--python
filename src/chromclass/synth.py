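"""Synthetic multi-cell-line chromatin dataset with planted ground truth.

The generator emulates the inputs of the region-classification pipeline:
binned chromatin-feature tracks whose enrichment marks planted active loci,
TRF peak sets with both global pairwise co-association (blocks of TRFs that
co-bind genome-wide) and planted many-TRF (HOT) loci, motif-site assignment
depleted at HOT loci, gene annotation with isoforms, and cross-cell-line
expression tables with planted module-transcript couplings of stated
population correlation.

Signal model: independent per-bin log-normal background; enrichment is a
plateau over each planted locus with short linear ramps outside, so the
planted extent is recoverable by a bin classifier.  TRF binding tracks are
sparse (mostly zero) with bumps at peaks, matching the zero-inflated
character of ChIP-seq binding signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    Annotation,
    BinGrid,
    GenomeSpec,
    Interval,
    PeakSet,
    RegionSet,
    SignalTrack,
    Transcript,
    intersect_intervals,
    normalize_intervals,
    total_bases,
)

FEATURES = ("DNase", "FAIRE", "H3K4me1", "H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3")
EXPRESSION_ASSAYS = (
    "polyA+ RNA-seq",
    "polyA- RNA-seq",
    "short RNA-seq",
    "polyA+ CAGE",
    "diTag",
)

# plateau amplitude of each feature over each planted category, in signal
# units on top of a log-normal background with median 1
_EFFECTS: dict[str, dict[str, float]] = {
    "active": {"DNase": 5, "FAIRE": 3, "H3K4me1": 2.5, "H3K4me3": 1, "H3K27ac": 3, "H3K36me3": 1},
    "promoter": {"DNase": 8, "FAIRE": 4, "H3K4me1": 2, "H3K4me3": 9, "H3K27ac": 5},
    "distal": {"DNase": 6, "FAIRE": 3, "H3K4me1": 9, "H3K4me3": 0.5, "H3K27ac": 6},
    "hot": {"DNase": 9, "FAIRE": 5, "H3K4me1": 3.5, "H3K4me3": 4, "H3K27ac": 5},
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic dataset; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_width: int = 100
    n_cell_lines: int = 5
    n_trfs: int = 20
    marks: tuple[str, ...] = FEATURES
    # planted region counts (whole genome) and length ranges in bp
    n_active_loci: int = 250
    active_len: tuple[int, int] = (400, 1200)
    private_len: tuple[int, int] = (300, 900)
    n_distal_loci: int = 60
    distal_len: tuple[int, int] = (600, 1500)
    n_hot_loci: int = 30
    hot_len: tuple[int, int] = (400, 1000)
    n_repeats: int = 40
    # signal model
    background_log_loc: float = 0.0
    background_log_scale: float = 0.5
    ramp: int = 150  # bp of linear ramp outside each planted locus
    # gene model
    gene_gap: tuple[int, int] = (20_000, 60_000)
    gene_len: tuple[int, int] = (5_000, 30_000)
    p_expressed: float = 0.75
    # co-association structure: two blocks of five TRFs; the rest singletons
    block_sizes: tuple[int, ...] = (5, 5)
    peak_share: float = 0.85  # P(block member binds a block locus)
    block_assign_p: float = 0.3  # P(generic locus assigned to a given block)
    n_private_loci: int = 80  # loci unique to each TRF (placed genome-wide)
    n_shared_loci: int = 8  # loci each TRF samples from the common active pool
    hot_n_trfs: tuple[int, int] = (8, 12)
    peak_len: tuple[int, int] = (200, 400)
    # motif model
    p_motif: float = 0.8
    p_motif_hot: float = 0.4
    n_background_motifs: int = 150  # genome-wide sites per TRF outside peaks
    # expression coupling
    n_couplings: int = 25
    rho_coupling: float = 0.9
    coupling_mark: str = "H3K4me1"
    coupling_assay: str = "polyA+ RNA-seq"

    def __post_init__(self) -> None:
        if not (-1 < self.rho_coupling < 1):
            raise ValueError("rho must be in (-1, 1)")
        for p in (self.p_motif, self.p_motif_hot, self.p_expressed, self.peak_share):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        for n in (
            self.n_active_loci, self.n_distal_loci, self.n_hot_loci,
            self.n_repeats, self.n_couplings, self.n_trfs, self.n_cell_lines,
        ):
            if n < 0:
                raise ValueError("counts must be >= 0")

    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i + 1}" for i in range(self.n_cell_lines)]

    @property
    def trf_names(self) -> list[str]:
        base = ["POL2RA", "CTCF"]
        extra = [f"TRF{i:02d}" for i in range(3, self.n_trfs + 1)]
        return (base + extra)[: self.n_trfs]


def _iv_to_json(iv: Interval) -> list:
    return [iv.chrom, iv.start, iv.end]


def _iv_from_json(x: list) -> Interval:
    return Interval(x[0], int(x[1]), int(x[2]))


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, serializable as JSON."""

    active_loci: dict[str, list[Interval]]  # per cell line, union of all bound loci
    promoter_loci: dict[str, list[Interval]]
    distal_loci: dict[str, list[Interval]]
    hot_loci: dict[str, list[Interval]]
    expressed_genes: dict[str, list[str]]
    blocks: list[list[str]]  # globally co-associating TRF groups
    peak_motif_flags: dict[str, dict[str, list[bool]]]  # cell -> trf -> per peak
    couplings: list[dict]  # module [c,s,e], transcript, mark, assay, rho

    def to_json(self) -> str:
        d = {
            "active_loci": {c: [_iv_to_json(i) for i in v] for c, v in self.active_loci.items()},
            "promoter_loci": {c: [_iv_to_json(i) for i in v] for c, v in self.promoter_loci.items()},
            "distal_loci": {c: [_iv_to_json(i) for i in v] for c, v in self.distal_loci.items()},
            "hot_loci": {c: [_iv_to_json(i) for i in v] for c, v in self.hot_loci.items()},
            "expressed_genes": self.expressed_genes,
            "blocks": self.blocks,
            "peak_motif_flags": self.peak_motif_flags,
            "couplings": self.couplings,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        loci = {
            k: {c: [_iv_from_json(x) for x in v] for c, v in d[k].items()}
            for k in ("active_loci", "promoter_loci", "distal_loci", "hot_loci")
        }
        return cls(
            active_loci=loci["active_loci"],
            promoter_loci=loci["promoter_loci"],
            distal_loci=loci["distal_loci"],
            hot_loci=loci["hot_loci"],
            expressed_genes=d["expressed_genes"],
            blocks=d["blocks"],
            peak_motif_flags=d["peak_motif_flags"],
            couplings=d["couplings"],
        )


@dataclass
class SynthDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SynthConfig
    genome: GenomeSpec
    grid: BinGrid
    annotation: Annotation
    feature_tracks: dict[str, dict[str, SignalTrack]]  # cell -> assay -> track
    trf_tracks: dict[str, dict[str, list[SignalTrack]]]  # cell -> trf -> replicates
    peaksets: dict[str, dict[str, PeakSet]]  # cell -> trf -> peaks
    conservation: SignalTrack  # cell-line independent, phastCons-like in [0, 1]
    repeats: list[Interval]
    motif_sites_known: dict[str, list[Interval]]  # trf -> sites
    motif_sites_novel: dict[str, list[Interval]]
    expression: pd.DataFrame  # transcripts x (cell line, assay)
    truth: PlantedTruth

    @property
    def cell_lines(self) -> list[str]:
        return self.config.cell_lines

    @property
    def trf_names(self) -> list[str]:
        return self.config.trf_names

    def all_peaks(self, cell_line: str) -> list[PeakSet]:
        return list(self.peaksets[cell_line].values())


# ---------------------------------------------------------------------------


def _make_annotation(rng: np.random.Generator, genome: GenomeSpec, cfg: SynthConfig) -> Annotation:
    """Place genes with 1-4 isoforms per gene along each chromosome."""
    transcripts: list[Transcript] = []
    gi = 0
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        pos = int(rng.integers(*cfg.gene_gap))
        while True:
            glen = int(rng.integers(*cfg.gene_len))
            if pos + glen > length - 1000:
                break
            gi += 1
            gene_id = f"G{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_iso = int(rng.integers(1, 5))
            for k in range(n_iso):
                # isoforms share the TSS-side end, vary the other end
                frac = 1.0 if k == 0 else float(rng.uniform(0.4, 1.0))
                tlen = max(500, int(glen * frac))
                if strand == "+":
                    ts, te = pos, pos + tlen
                else:
                    ts, te = pos + glen - tlen, pos + glen
                n_ex = int(rng.integers(2, 7))
                cuts = np.sort(rng.choice(np.arange(1, tlen // 100), size=2 * n_ex - 2, replace=False)) * 100
                bounds = np.concatenate([[0], cuts, [tlen]])
                exons = tuple(
                    (ts + int(bounds[2 * j]), ts + int(bounds[2 * j + 1]))
                    for j in range(n_ex)
                )
                transcripts.append(
                    Transcript(
                        transcript_id=f"{gene_id}.T{k + 1}",
                        gene_id=gene_id,
                        chrom=chrom,
                        strand=strand,
                        exons=exons,
                    )
                )
            pos += glen + int(rng.integers(*cfg.gene_gap))
    return Annotation(transcripts)


def _intergenic_gaps(genome: GenomeSpec, annotation: Annotation, margin: int) -> list[Interval]:
    spans = annotation.gene_spans()
    gaps = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        edges = [(s.start, s.end) for s in spans if s.chrom == chrom]
        prev = 0
        for s, e in sorted(edges):
            if s - prev > 2 * margin:
                gaps.append(Interval(chrom, prev + margin, s - margin))
            prev = max(prev, e)
        if length - prev > 2 * margin:
            gaps.append(Interval(chrom, prev + margin, length - margin))
    return gaps


def _snap(s: int, L: int, width: int) -> tuple[int, int]:
    """Align a locus to bin boundaries (callers operate at bin granularity)."""
    s = (s // width) * width
    L = max(width, int(round(L / width)) * width)
    return s, L


def _place_in_gaps(
    rng: np.random.Generator, gaps: list[Interval], n: int, len_range: tuple[int, int],
    occupied: list[Interval], width: int = 100,
) -> list[Interval]:
    """Place n non-overlapping bin-aligned loci inside the given gaps."""
    out: list[Interval] = []
    weights = np.array([len(g) for g in gaps], dtype=float)
    weights /= weights.sum()
    tries = 0
    while len(out) < n and tries < 50 * n:
        tries += 1
        g = gaps[int(rng.choice(len(gaps), p=weights))]
        L = int(rng.integers(*len_range))
        if len(g) <= L + width:
            continue
        s = int(rng.integers(g.start, g.end - L))
        s, L = _snap(s, L, width)
        if s < g.start or s + L > g.end:
            continue
        iv = Interval(g.chrom, s, s + L)
        if any(iv.overlaps(o) for o in occupied) or any(iv.overlaps(o) for o in out):
            continue
        out.append(iv)
    if len(out) < n:
        raise ValueError(
            f"could not place {n} loci of length {len_range} in the available gaps"
        )
    return out


class _Occupancy:
    """Bin-resolution occupancy mask so planted loci never stack."""

    def __init__(self, grid: BinGrid):
        self.grid = grid
        self.mask = np.zeros(grid.n_bins, dtype=bool)

    def add(self, intervals: Sequence[Interval]) -> None:
        for iv in intervals:
            self.mask[self.grid.bins_in_range(iv.chrom, iv.start, iv.end)] = True

    def overlaps(self, iv: Interval) -> bool:
        return bool(self.mask[self.grid.bins_in_range(iv.chrom, iv.start, iv.end)].any())


def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: GenomeSpec,
    occ: _Occupancy,
    n: int,
    len_range: tuple[int, int],
) -> list[Interval]:
    """Place n loci anywhere, avoiding (and then claiming) occupied bins."""
    out: list[Interval] = []
    lengths = np.array(genome.chrom_lengths, dtype=float)
    p = lengths / lengths.sum()
    tries = 0
    width = occ.grid.width
    while len(out) < n and tries < 200 * n:
        tries += 1
        ci = int(rng.choice(len(lengths), p=p))
        L = int(rng.integers(*len_range))
        s = int(rng.integers(0, genome.chrom_lengths[ci] - L - width))
        s, L = _snap(s, L, width)
        iv = Interval(genome.chrom_names[ci], s, s + L)
        if occ.overlaps(iv):
            continue
        occ.add([iv])
        out.append(iv)
    if len(out) < n:
        raise ValueError(f"could not place {n} non-overlapping loci; genome too crowded")
    return out


def _place_anywhere(
    rng: np.random.Generator, genome: GenomeSpec, n: int, len_range: tuple[int, int],
    avoid: list[Interval], width: int | None = None,
) -> list[Interval]:
    out: list[Interval] = []
    lengths = np.array(genome.chrom_lengths, dtype=float)
    p = lengths / lengths.sum()
    tries = 0
    while len(out) < n and tries < 100 * n:
        tries += 1
        ci = int(rng.choice(len(lengths), p=p))
        chrom = genome.chrom_names[ci]
        L = int(rng.integers(*len_range))
        s = int(rng.integers(0, genome.chrom_lengths[ci] - L - (width or 0)))
        if width:
            s, L = _snap(s, L, width)
        iv = Interval(chrom, s, s + L)
        if any(iv.overlaps(o) for o in avoid) or any(iv.overlaps(o) for o in out):
            continue
        out.append(iv)
    if len(out) < n:
        raise ValueError(f"could not place {n} loci; genome too crowded")
    return out


def _add_plateau(
    values: np.ndarray, grid: BinGrid, iv: Interval, amplitude: float, ramp: int
) -> None:
    """Add a plateau of `amplitude` over iv with linear ramps of `ramp` bp."""
    chrom_len = grid.genome.length(iv.chrom)
    lo = max(0, iv.start - ramp)
    hi = min(chrom_len, iv.end + ramp)
    idx = grid.bins_in_range(iv.chrom, lo, hi)
    off = grid.chrom_offset(iv.chrom)
    centers = (idx - off) * grid.width + grid.width / 2.0
    prof = np.ones_like(centers, dtype=float)
    if ramp > 0:
        left = centers < iv.start
        prof[left] = np.clip((centers[left] - (iv.start - ramp)) / ramp, 0, 1)
        right = centers >= iv.end
        prof[right] = np.clip(((iv.end + ramp) - centers[right]) / ramp, 0, 1)
    values[idx] += amplitude * prof


def _coupled_response(rng: np.random.Generator, x: np.ndarray, rho: float) -> np.ndarray:
    """Affine response of x with Gaussian noise calibrated so the population
    correlation corr(x, y) equals rho (sign included); rho = 0 gives a fully
    independent response of comparable scale."""
    x = np.asarray(x, dtype=float)
    mx, sx = float(np.mean(x)), float(np.std(x))
    if sx == 0 or rho == 0:
        scale = sx if sx > 0 else 1.0
        return rng.normal(mx, scale, size=len(x))
    sigma = sx * np.sqrt(1.0 / rho**2 - 1.0)
    return np.sign(rho) * x + rng.normal(0.0, sigma, size=len(x))


def generate_dataset(config: SynthConfig | None = None, seed: int | None = None) -> SynthDataset:
    """Generate the full synthetic dataset; fully reproducible from the seed."""
    cfg = config or SynthConfig()
    if seed is not None:
        cfg = SynthConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)

    genome = GenomeSpec(
        tuple(f"chr{i + 1}" for i in range(cfg.n_chroms)),
        tuple([cfg.chrom_length] * cfg.n_chroms),
    )
    grid = BinGrid(genome, cfg.bin_width)
    annotation = _make_annotation(rng, genome, cfg)
    gene_spans = annotation.gene_spans()

    # -- global locus placement --------------------------------------------
    gaps = _intergenic_gaps(genome, annotation, margin=12_000)
    if not gaps:
        raise ValueError("no intergenic gaps >= 24 kb; genome too small for distal loci")
    distal_loci = _place_in_gaps(
        rng, gaps, cfg.n_distal_loci, cfg.distal_len, [], width=cfg.bin_width
    )
    hot_gap = _place_in_gaps(
        rng, gaps, cfg.n_hot_loci // 2, cfg.hot_len, distal_loci, width=cfg.bin_width
    )
    hot_any = _place_anywhere(
        rng, genome, cfg.n_hot_loci - len(hot_gap), cfg.hot_len,
        distal_loci + hot_gap, width=cfg.bin_width,
    )
    hot_loci = sorted(hot_gap + hot_any, key=lambda iv: (iv.chrom, iv.start))
    occ = _Occupancy(grid)
    occ.add(distal_loci + hot_loci)
    generic_loci = _place_nonoverlapping(rng, genome, occ, cfg.n_active_loci, cfg.active_len)
    repeats = _place_nonoverlapping(rng, genome, occ, cfg.n_repeats, (300, 1000))

    # -- TRF block structure ------------------------------------------------
    trfs = cfg.trf_names
    blocks: list[list[str]] = []
    cursor = 2  # POL2RA and CTCF stay singletons
    for bs in cfg.block_sizes:
        blocks.append(trfs[cursor : cursor + bs])
        cursor += bs
    singleton_trfs = trfs[:2] + trfs[cursor:]
    # assign each generic locus to at most one block
    block_loci: list[list[Interval]] = [[] for _ in blocks]
    for iv in generic_loci:
        u = rng.random()
        for bi in range(len(blocks)):
            if u < cfg.block_assign_p * (bi + 1):
                block_loci[bi].append(iv)
                break
    # loci unique to each TRF: the genome-wide binding a TRF does on its own,
    # which keeps global co-association specific to the planted blocks
    private_loci: dict[str, list[Interval]] = {
        trf: _place_nonoverlapping(rng, genome, occ, cfg.n_private_loci, cfg.private_len)
        for trf in trfs
    }

    # -- per-gene expression status and levels -------------------------------
    gene_ids = annotation.gene_ids
    base_expr = {g: float(rng.lognormal(1.2, 0.6)) for g in gene_ids}
    expressed: dict[str, set[str]] = {}
    for cl in cfg.cell_lines:
        expressed[cl] = {g for g in gene_ids if rng.random() < cfg.p_expressed}

    tss_by_gene: dict[str, tuple[str, int]] = {}
    for g in gene_ids:
        t0 = annotation.gene_transcripts(g)[0]
        tss_by_gene[g] = (t0.chrom, t0.tss)

    # -- per cell line: activity flags, amplitudes, peaks, tracks ------------
    feature_tracks: dict[str, dict[str, SignalTrack]] = {}
    trf_tracks: dict[str, dict[str, list[SignalTrack]]] = {}
    peaksets: dict[str, dict[str, PeakSet]] = {}
    truth_active: dict[str, list[Interval]] = {}
    truth_prom: dict[str, list[Interval]] = {}
    truth_distal: dict[str, list[Interval]] = {}
    truth_hot: dict[str, list[Interval]] = {}
    peak_motif_flags: dict[str, dict[str, list[bool]]] = {}
    motif_known: dict[str, list[Interval]] = {t: [] for t in trfs}
    motif_novel: dict[str, list[Interval]] = {t: [] for t in trfs}
    distal_amp: dict[str, np.ndarray] = {}

    for icl, cl in enumerate(cfg.cell_lines):
        generic_on = [iv for iv in generic_loci if rng.random() < 0.8]
        hot_on = [iv for iv in hot_loci if rng.random() < 0.9]
        private_on = {
            trf: [iv for iv in private_loci[trf] if rng.random() < 0.8]
            for trf in trfs
        }
        prom_on = []
        for g in sorted(expressed[cl]):
            chrom, tss = tss_by_gene[g]
            length = genome.length(chrom)
            prom_on.append(Interval(chrom, max(0, tss - 500), min(length, tss + 500)))
        # distal amplitude varies across cell lines (drives the couplings);
        # the first cell line keeps all distal loci strongly marked
        if icl == 0:
            amps = rng.uniform(1.0, 2.0, size=len(distal_loci))
        else:
            amps = rng.uniform(0.15, 2.0, size=len(distal_loci))
        distal_amp[cl] = amps
        distal_on = list(distal_loci)

        all_private_on = [iv for trf in trfs for iv in private_on[trf]]
        truth_prom[cl] = normalize_intervals(prom_on)
        truth_distal[cl] = distal_on
        truth_hot[cl] = hot_on
        truth_active[cl] = normalize_intervals(
            generic_on + hot_on + prom_on + distal_on + all_private_on
        )

        # ---- peaks -------------------------------------------------------
        binding: dict[str, list[tuple[Interval, float]]] = {t: [] for t in trfs}
        anchors: dict[tuple[str, int], Interval] = {}

        def bind(trf: str, locus: Interval, strength: float = 1.0,
                 anchored: bool = False) -> None:
            val = float(rng.uniform(8, 30)) * strength
            if anchored:
                # co-binding TRFs share the site, up to a small jitter
                key = (locus.chrom, locus.start)
                a = anchors.get(key)
                if a is None:
                    L = min(int(rng.integers(*cfg.peak_len)), len(locus))
                    lo, hi = locus.start, max(locus.start + 1, locus.end - L)
                    s = int(rng.integers(lo, hi)) if hi > lo else lo
                    a = Interval(locus.chrom, s, s + L)
                    anchors[key] = a
                j = int(rng.integers(-50, 51))
                s = max(0, a.start + j)
                binding[trf].append((Interval(locus.chrom, s, s + len(a), value=val), val))
                return
            L = int(rng.integers(*cfg.peak_len))
            L = min(L, len(locus))
            lo = locus.start
            hi = max(lo + 1, locus.end - L)
            s = int(rng.integers(lo, hi)) if hi > lo else lo
            binding[trf].append((Interval(locus.chrom, s, s + L, value=val), val))

        generic_on_set = {(iv.chrom, iv.start) for iv in generic_on}
        for bi, block in enumerate(blocks):
            for locus in block_loci[bi]:
                if (locus.chrom, locus.start) not in generic_on_set:
                    continue
                for trf in block:
                    if rng.random() < cfg.peak_share:
                        bind(trf, locus, anchored=True)
        for trf in trfs:
            for locus in private_on[trf]:
                if rng.random() < 0.95:
                    bind(trf, locus)
            pool = generic_on + distal_on
            k = min(cfg.n_shared_loci, len(pool))
            for j in rng.choice(len(pool), size=k, replace=False):
                bind(trf, pool[int(j)])
        for g in sorted(expressed[cl]):
            chrom, tss = tss_by_gene[g]
            if rng.random() < 0.9:
                length = genome.length(chrom)
                bind("POL2RA", Interval(chrom, max(0, tss - 400), min(length, tss + 400)))
        for locus, amp in zip(distal_on, distal_amp[cl]):
            n_extra = int(rng.integers(2, 6))
            for j in rng.choice(len(singleton_trfs), size=min(n_extra, len(singleton_trfs)), replace=False):
                if amp > 0.5:
                    bind(singleton_trfs[int(j)], locus)
        for locus in hot_on:
            k = int(rng.integers(*cfg.hot_n_trfs))
            for j in rng.choice(len(trfs), size=min(k, len(trfs)), replace=False):
                bind(trfs[int(j)], locus, strength=1.5, anchored=True)
        # CTCF also binds scattered sites (for interposition statistics)
        ctcf_extra = _place_anywhere(rng, genome, 150, (200, 400), [])
        for iv in ctcf_extra:
            bind("CTCF", iv)

        peaksets[cl] = {}
        peak_motif_flags[cl] = {}
        hot_on_sorted = normalize_intervals(hot_on)
        for trf in trfs:
            ps = PeakSet(trf=trf, cell_line=cl, peaks=[iv for iv, _ in binding[trf]])
            peaksets[cl][trf] = ps
            flags = []
            for p in ps.peaks:
                in_hot = any(p.overlaps(h) for h in hot_on_sorted)
                p_m = cfg.p_motif_hot if in_hot else cfg.p_motif
                has = bool(rng.random() < p_m)
                flags.append(has)
                if has and len(p) > 12:
                    s = int(rng.integers(p.start, p.end - 10))
                    site = Interval(p.chrom, s, s + 10)
                    (motif_known if rng.random() < 0.5 else motif_novel)[trf].append(site)
            peak_motif_flags[cl][trf] = flags

        # ---- feature tracks ----------------------------------------------
        feature_tracks[cl] = {}
        cat_loci = {
            "active": [(iv, 1.0) for iv in generic_on + all_private_on],
            "promoter": [(iv, 1.0) for iv in prom_on],
            "distal": list(zip(distal_on, amps)),
            "hot": [(iv, 1.0) for iv in hot_on],
        }
        for mark in cfg.marks:
            vals = rng.lognormal(cfg.background_log_loc, cfg.background_log_scale, grid.n_bins)
            for cat, loci in cat_loci.items():
                eff = _EFFECTS[cat].get(mark, 0.0)
                if eff == 0:
                    continue
                for iv, amp in loci:
                    jitter = float(rng.uniform(0.85, 1.15))
                    _add_plateau(vals, grid, iv, eff * amp * jitter, cfg.ramp)
            feature_tracks[cl][mark] = SignalTrack(grid, vals, assay=mark, cell_line=cl)

        # ---- TRF binding tracks (replicates) ------------------------------
        trf_tracks[cl] = {}
        for trf in trfs:
            n_rep = 2 if rng.random() < 0.4 else 1
            reps = []
            for _ in range(n_rep):
                vals = np.zeros(grid.n_bins)
                noisy = rng.random(grid.n_bins) < 0.08
                vals[noisy] = rng.exponential(0.3, int(noisy.sum()))
                scale = float(rng.uniform(0.8, 1.2))
                for p, val in binding[trf]:
                    _add_plateau(vals, grid, p, val * scale, 100)
                reps.append(SignalTrack(grid, vals, assay=f"{trf} ChIP", cell_line=cl))
            trf_tracks[cl][trf] = reps

    # deduplicate motif sites per TRF
    for trf in trfs:
        motif_known[trf] = normalize_intervals(motif_known[trf])
        motif_novel[trf] = normalize_intervals(motif_novel[trf])
        bg = _place_anywhere(rng, genome, cfg.n_background_motifs, (10, 11), [])
        motif_known[trf] = normalize_intervals(motif_known[trf] + bg)

    # -- conservation (phastCons-like, in [0, 1], cell-line independent) ----
    cons = rng.beta(2, 8, grid.n_bins)
    for iv in distal_loci:
        _add_plateau(cons, grid, iv, 0.7, cfg.ramp)
    for g in gene_ids:
        chrom, tss = tss_by_gene[g]
        length = genome.length(chrom)
        _add_plateau(cons, grid, Interval(chrom, max(0, tss - 300), min(length, tss + 300)), 0.35, cfg.ramp)
    conservation = SignalTrack(grid, np.clip(cons, 0, 1), assay="conservation")

    # -- expression matrix ---------------------------------------------------
    tids = [t.transcript_id for t in annotation.transcripts]
    cols = pd.MultiIndex.from_product(
        [cfg.cell_lines, EXPRESSION_ASSAYS], names=["cell_line", "assay"]
    )
    n_t = len(tids)
    n_col = len(cols)
    tf = rng.uniform(0.3, 1.0, size=n_t)
    base = np.array([base_expr[t.gene_id] for t in annotation.transcripts])
    on = np.zeros((n_t, cfg.n_cell_lines), dtype=bool)
    for j, cl in enumerate(cfg.cell_lines):
        on[:, j] = [t.gene_id in expressed[cl] for t in annotation.transcripts]
    on_cols = np.repeat(on, len(EXPRESSION_ASSAYS), axis=1)
    vals = np.where(
        on_cols,
        (base * tf)[:, None] * rng.lognormal(0, 0.3, size=(n_t, n_col)),
        rng.exponential(0.05, size=(n_t, n_col)),
    )
    expr = pd.DataFrame(vals, index=tids, columns=cols)

    # -- planted DRM-target couplings ---------------------------------------
    couplings: list[dict] = []
    mark = cfg.coupling_mark
    mark_summary = {}
    for cl in cfg.cell_lines:
        track = feature_tracks[cl][mark]
        mark_summary[cl] = track
    tss_list = [(t.chrom, t.tss, t.transcript_id) for t in annotation.transcripts]
    candidates_by_locus: list[list[str]] = []
    for iv in distal_loci:
        near = [
            tid for chrom, tss, tid in tss_list
            if chrom == iv.chrom and min(abs(tss - iv.start), abs(tss - iv.end)) <= 900_000
        ]
        candidates_by_locus.append(near)
    order = rng.permutation(len(distal_loci))
    used_t: set[str] = set()
    for li in order:
        if len(couplings) >= cfg.n_couplings:
            break
        near = [t for t in candidates_by_locus[int(li)] if t not in used_t]
        if not near:
            continue
        tid = near[int(rng.integers(len(near)))]
        used_t.add(tid)
        iv = distal_loci[int(li)]
        idx = grid.bins_in_range(iv.chrom, iv.start, iv.end)
        x = np.array([float(mark_summary[cl].values[idx].mean()) for cl in cfg.cell_lines])
        y = np.clip(_coupled_response(rng, x, cfg.rho_coupling), 0.0, None)
        for cl, v in zip(cfg.cell_lines, y):
            expr.loc[tid, (cl, cfg.coupling_assay)] = float(v)
        couplings.append(
            {
                "module": _iv_to_json(iv),
                "transcript": tid,
                "mark": mark,
                "assay": cfg.coupling_assay,
                "rho": cfg.rho_coupling,
            }
        )
    if len(couplings) < cfg.n_couplings:
        warnings.warn(
            f"only {len(couplings)} of {cfg.n_couplings} couplings could be planted"
        )

    truth = PlantedTruth(
        active_loci=truth_active,
        promoter_loci=truth_prom,
        distal_loci=truth_distal,
        hot_loci=truth_hot,
        expressed_genes={cl: sorted(v) for cl, v in expressed.items()},
        blocks=[list(b) for b in blocks],
        peak_motif_flags=peak_motif_flags,
        couplings=couplings,
    )
    return SynthDataset(
        config=cfg,
        genome=genome,
        grid=grid,
        annotation=annotation,
        feature_tracks=feature_tracks,
        trf_tracks=trf_tracks,
        peaksets=peaksets,
        conservation=conservation,
        repeats=repeats,
        motif_sites_known=motif_known,
        motif_sites_novel=motif_novel,
        expression=expr,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Module-level generator for the coupling-recovery study


def generate_pair_study(
    seed: int = 0,
    n_cell_lines: int = 9,
    n_modules: int = 250,
    n_transcripts: int = 105,
    n_planted: int = 50,
    rho: float = 0.98,
    chrom_length: int = 10_000_000,
    mark: str = "H3K4me1",
    assay: str = "polyA+ RNA-seq",
):
    """Module-level study: modules and transcripts on one chromosome with a
    stated number of planted couplings of population correlation rho.

    Returns (modules, module_summaries, annotation, expression, planted)
    where module_summaries is a DataFrame modules x cell lines of mark
    signal, expression a transcripts x (cell line, assay) DataFrame, and
    planted the list of (module index, transcript id) truth couplings.
    """
    rng = np.random.default_rng(seed)
    cells = [f"CL{i + 1}" for i in range(n_cell_lines)]
    step = chrom_length // (n_modules + 1)
    modules = [Interval("chr1", (i + 1) * step, (i + 1) * step + 500) for i in range(n_modules)]
    tstep = chrom_length // (n_transcripts + 1)
    transcripts = []
    for j in range(n_transcripts):
        tss = (j + 1) * tstep
        transcripts.append(
            Transcript(
                transcript_id=f"T{j:04d}",
                gene_id=f"G{j:04d}",
                chrom="chr1",
                strand="+",
                exons=((tss, tss + 5_000),),
            )
        )
    annotation = Annotation(transcripts)
    # near-Gaussian positive signal: comfortably passes the level/fold
    # filters while matching the normality the Fisher-transform p assumes
    X = np.abs(rng.normal(5.0, 2.0, size=(n_modules, n_cell_lines)))
    msum = pd.DataFrame(X, columns=cells)
    cols = pd.MultiIndex.from_product([cells, [assay]], names=["cell_line", "assay"])
    Y = np.abs(rng.normal(5.0, 2.0, size=(n_transcripts, n_cell_lines)))
    expr = pd.DataFrame(Y, index=[t.transcript_id for t in transcripts], columns=cols)
    # plant couplings between nearby (<= 1 Mbp) module/transcript pairs
    planted: list[tuple[int, str]] = []
    used: set[str] = set()
    order = rng.permutation(n_modules)
    for mi in order:
        if len(planted) >= n_planted:
            break
        iv = modules[int(mi)]
        near = [
            t.transcript_id
            for t in transcripts
            if t.transcript_id not in used and abs(t.tss - iv.start) <= 990_000
        ]
        if not near:
            continue
        tid = near[int(rng.integers(len(near)))]
        used.add(tid)
        x = X[int(mi)]
        y = np.clip(_coupled_response(rng, x, rho), 0.0, None)
        for cl, v in zip(cells, y):
            expr.loc[tid, (cl, assay)] = float(v)
        planted.append((int(mi), tid))
    return modules, msum, annotation, expr, planted


# ---------------------------------------------------------------------------
# Truth evaluation


@dataclass
class PrecisionRecall:
    base_precision: float
    base_recall: float
    element_precision: float
    element_recall: float


def truth_eval(
    calls: RegionSet | Sequence[Interval], truth: Sequence[Interval]
) -> PrecisionRecall:
    """Base- and element-level precision/recall of calls against truth.

    Base level: precision = overlapping bases / called bases, recall =
    overlapping bases / truth bases.  Element level uses >= 1 base overlap.
    Empty calls give recall 0 and (vacuous) precision 1, with a warning.
    """
    call_ivs = calls.regions if isinstance(calls, RegionSet) else list(calls)
    call_ivs = normalize_intervals(call_ivs)
    truth_ivs = normalize_intervals(truth)
    if not call_ivs:
        warnings.warn("empty call set: precision is vacuous (reported as 1)")
        return PrecisionRecall(1.0, 0.0, 1.0, 0.0)
    if not truth_ivs:
        warnings.warn("empty truth set: recall is vacuous (reported as 1)")
        return PrecisionRecall(0.0, 1.0, 0.0, 1.0)
    inter = intersect_intervals(call_ivs, truth_ivs)
    ib = total_bases(inter)
    cb = total_bases(call_ivs)
    tb = total_bases(truth_ivs)
    hit_t = sum(1 for t in truth_ivs if any(t.overlaps(c) for c in call_ivs))
    hit_c = sum(1 for c in call_ivs if any(c.overlaps(t) for t in truth_ivs))
    return PrecisionRecall(
        base_precision=ib / cb,
        base_recall=ib / tb,
        element_precision=hit_c / len(call_ivs),
        element_recall=hit_t / len(truth_ivs),
    )
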