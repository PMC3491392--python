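import numpy as np
import pandas as pd
import pytest

from chromclass.barbir import ScoreTrack
from chromclass.genome import (
    Annotation, BinGrid, GenomeSpec, Interval, PeakSet, RegionSet, Transcript,
)
from chromclass.prmdrm import (
    call_drms,
    call_prms,
    expressed_transcripts,
    expressed_tss_bins,
    prm_negative_bins,
    prm_threshold,
    tss_flank_bins,
)


@pytest.fixture
def grid():
    return BinGrid(GenomeSpec(("chr1",), (200_000,)), 100)


def expr_frame(rows: dict) -> pd.DataFrame:
    assays = ["polyA+ RNA-seq", "polyA+ CAGE", "diTag"]
    cols = pd.MultiIndex.from_product([["CL1"], assays], names=["cell_line", "assay"])
    return pd.DataFrame(
        [rows[t] for t in rows], index=list(rows), columns=cols, dtype=float
    )


class TestExpressedRule:
    def test_inclusive_rpkm_threshold(self):
        df = expr_frame({"T1": [1.0, 0.0, 0.0]})
        assert expressed_transcripts(df, "CL1") == {"T1"}

    def test_or_rule_via_cage(self):
        df = expr_frame({"T1": [0.5, 1.2, 0.0]})
        assert expressed_transcripts(df, "CL1") == {"T1"}

    def test_below_both_thresholds_not_expressed(self):
        df = expr_frame({"T1": [0.5, 0.2, 0.9]})
        assert expressed_transcripts(df, "CL1") == set()

    def test_missing_cell_line_is_an_error(self):
        df = expr_frame({"T1": [1.0, 0.0, 0.0]})
        with pytest.raises(KeyError):
            expressed_transcripts(df, "CL9")

    def test_tss_bins_located_strand_aware(self, grid):
        ann = Annotation([
            Transcript("T1", "G1", "chr1", "+", ((50_000, 60_000),)),
            Transcript("T2", "G2", "chr1", "-", ((80_000, 90_050),)),
        ])
        df = expr_frame({"T1": [2.0, 0, 0], "T2": [2.0, 0, 0]})
        bins = expressed_tss_bins(ann, df, grid, "CL1")
        # + strand TSS at 50,000 -> bin 500; - strand TSS at 90,049 -> bin 900
        assert bins.tolist() == [500, 900]


class TestTssFlanks:
    def test_windows_are_strand_aware(self, grid):
        ann = Annotation([Transcript("T1", "G1", "chr1", "+", ((50_000, 60_000),))])
        bins = set(tss_flank_bins(ann, grid).tolist())
        assert grid.bin_index("chr1", 50_000 - 3000) in bins  # 3 kb upstream
        assert grid.bin_index("chr1", 50_000 + 500) in bins   # 500 bp downstream
        assert grid.bin_index("chr1", 50_000 - 6000) not in bins
        assert grid.bin_index("chr1", 50_000 + 1500) not in bins
        # 100 bp downstream is inside the excluded 0-200 gap... the bin
        # containing it is included only via the 200-1000 window overlap
        minus = Annotation([Transcript("T1", "G1", "chr1", "-", ((50_000, 60_000),))])
        mbins = set(tss_flank_bins(minus, grid).tolist())
        tss = 59_999
        assert grid.bin_index("chr1", tss + 3000) in mbins  # upstream flips
        assert grid.bin_index("chr1", tss - 500) in mbins


class TestNegativeBins:
    def make_inputs(self, grid):
        ann = Annotation([
            Transcript("T1", "G1", "chr1", "+", ((100_000, 110_000),)),
        ])
        peaks = [
            PeakSet("GATA1", "CL1", [Interval("chr1", 10_000, 10_300)]),  # 90 kb from gene
            PeakSet("POL2RA", "CL1", [Interval("chr1", 20_000, 20_300)]),
            PeakSet("TRF03", "CL1", [Interval("chr1", 95_000, 95_300)]),  # 4.7 kb from gene
        ]
        return ann, peaks

    def test_three_subsets_follow_their_rules(self, grid):
        ann, peaks = self.make_inputs(grid)
        negs = prm_negative_bins(grid, peaks, ann, n_neg=300, seed=0)
        # subset 2: GATA1 bins are >= 10 kb from the gene; POL2RA and the
        # close TRF03 peak are excluded
        assert set(negs.distal_peaks.tolist()) == {100, 101, 102}
        # subset 1 never overlaps any peak
        peak_bins = {100, 101, 102, 103, 200, 201, 202, 203, 950, 951, 952, 953}
        assert not (set(negs.no_binding.tolist()) & peak_bins)
        # subset 3 sits in the TSS-flank windows, outside peaks
        for b in negs.tss_flank.tolist():
            chrom, s, e = grid.bin_bounds(b)
            assert 95_000 <= s <= 101_000

    def test_empty_subset_is_reported_by_name(self, grid):
        ann = Annotation([Transcript("T1", "G1", "chr1", "+", ((100_000, 110_000),))])
        peaks = [PeakSet("POL2RA", "CL1", [Interval("chr1", 20_000, 20_300)])]
        with pytest.raises(ValueError, match="distal_peaks"):
            prm_negative_bins(grid, peaks, ann, n_neg=300, seed=0)


class TestPrmThreshold:
    def test_exactly_one_percent_above(self):
        scores = np.array([0.01 * i for i in range(1, 101)])
        t = prm_threshold([scores])
        assert t == pytest.approx(0.99)
        assert int((scores > t).sum()) == 1

    def test_order_statistic_at_n200(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0, 1, 200))
        t = prm_threshold([scores])
        assert t == pytest.approx(np.sort(scores)[197])
        assert int((scores > t).sum()) == 2

    def test_tied_scores_resolve_to_fewer_above_with_warning(self):
        scores = np.full(150, 0.4)
        with pytest.warns(UserWarning, match="tied"):
            t = prm_threshold([scores])
        assert t == 0.4 and int((scores > t).sum()) == 0

    def test_mean_over_folds_and_pooled_variant(self):
        a = np.linspace(0, 1, 101)[1:]
        b = np.linspace(0, 0.5, 101)[1:]
        t = prm_threshold([a, b])
        assert t == pytest.approx((np.sort(a)[98] + np.sort(b)[98]) / 2)
        tp = prm_threshold([a, b], pooled=True)
        pooled = np.sort(np.concatenate([a, b]))
        assert tp == pytest.approx(pooled[200 - 2 - 1])

    def test_too_few_negatives_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            prm_threshold([np.ones(50)])


class TestCallPrmDrm:
    def test_prm_strict_boundary(self, grid):
        scores = np.zeros(grid.n_bins)
        scores[[5, 6]] = [0.71, 0.70]
        prms = call_prms(ScoreTrack(grid, scores, kind="PRM"), threshold=0.70)
        assert prms.bin_indices.tolist() == [5]

    def test_drm_rules(self, grid):
        ann = Annotation([
            Transcript("T1", "G1", "chr1", "+", ((100_000, 110_000),)),
        ])
        # BAR bins: one 50 kb away (kept), one intronic (dropped), one at
        # 9,950 bp gap (dropped), one at exactly 10,000 (kept)
        bar_bins = np.array([
            grid.bin_index("chr1", 50_000),
            grid.bin_index("chr1", 105_000),
            grid.bin_index("chr1", 90_000),   # gap to gene = 9,900 < 10,000
            grid.bin_index("chr1", 89_900),   # gap exactly 10,000
        ])
        bars = RegionSet.from_bins(grid, bar_bins, "BAR")
        prms = RegionSet.from_bins(grid, np.array([], dtype=np.int64), "PRM")
        drms = call_drms(bars, prms, ann, min_dist=10_000)
        kept = drms.bin_indices.tolist()
        assert grid.bin_index("chr1", 50_000) in kept
        assert grid.bin_index("chr1", 89_900) in kept
        assert grid.bin_index("chr1", 105_000) not in kept
        assert grid.bin_index("chr1", 90_000) not in kept

    def test_prm_bins_are_excluded_from_drms(self, grid):
        ann = Annotation([Transcript("T1", "G1", "chr1", "+", ((150_000, 160_000),))])
        bar_bins = np.array([10, 11, 12])
        bars = RegionSet.from_bins(grid, bar_bins, "BAR")
        prms = RegionSet.from_bins(grid, np.array([11]), "PRM")
        drms = call_drms(bars, prms, ann, min_dist=10_000)
        assert drms.bin_indices.tolist() == [10, 12]
        assert not (set(drms.bin_indices.tolist()) & set(prms.bin_indices.tolist()))


def test_small_dataset_prm_drm_disjointness(small_dataset):
    """PRM and DRM never share a bin and DRM is a subset of BAR."""
    from chromclass.pipeline import PipelineConfig, stage_bar_bir, stage_prm_drm

    cfg = PipelineConfig(seed=11, n_pos=1200, n_neg=1200, n_trees=40)
    cl = small_dataset.cell_lines[0]
    bb = stage_bar_bir(small_dataset, cfg, cl)
    pp = stage_prm_drm(small_dataset, cfg, cl, bb["bars"])
    bar = bb["bars"].bin_index_set()
    prm = pp["prms"].bin_index_set()
    drm = pp["drms"].bin_index_set()
    assert not (prm & drm)
    assert drm <= bar
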