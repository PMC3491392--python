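import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromclass.genome import (
    BinGrid,
    GenomeSpec,
    Interval,
    PeakSet,
    average_signal,
    bins_overlapping,
    distance_to_features,
    intersect_intervals,
    make_bins,
    merge_intervals,
    normalize_intervals,
    subtract_intervals,
    total_bases,
)
from chromclass.genome import InvalidInputError


class TestMakeBins:
    @pytest.mark.parametrize(
        "lengths,width,expected",
        [
            ((250,), 100, 3),
            ((100,), 100, 1),
            ((300, 50), 100, 4),
            ((99,), 100, 1),
            ((101,), 100, 2),
        ],
    )
    def test_bin_count_matches_ceil_division(self, lengths, width, expected):
        genome = GenomeSpec(tuple(f"c{i}" for i in range(len(lengths))), lengths)
        grid = make_bins(genome, width)
        assert grid.n_bins == expected
        # independent oracle
        assert grid.n_bins == sum(-(-l // width) for l in lengths)

    def test_partition_bounds(self):
        grid = make_bins(GenomeSpec(("chr1",), (250,)), 100)
        assert [grid.bin_bounds(i) for i in range(3)] == [
            ("chr1", 0, 100), ("chr1", 100, 200), ("chr1", 200, 250),
        ]
        assert grid.is_partial_bin(2) and not grid.is_partial_bin(0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            make_bins(GenomeSpec(("c",), (100,)), 0)
        with pytest.raises(InvalidInputError):
            GenomeSpec(("a", "a"), (1, 2))
        with pytest.raises(InvalidInputError):
            GenomeSpec(("a",), (0,))

    @given(
        lengths=st.lists(st.integers(1, 5000), min_size=1, max_size=4),
        width=st.integers(1, 700),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_binning_is_a_partition(self, lengths, width):
        """Every base belongs to exactly one bin: per-chromosome bin lengths
        sum to the chromosome length."""
        genome = GenomeSpec(tuple(f"c{i}" for i in range(len(lengths))), tuple(lengths))
        grid = make_bins(genome, width)
        bl = grid.bin_lengths()
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            off = grid.chrom_offset(chrom)
            n = grid.chrom_nbins(chrom)
            assert bl[off : off + n].sum() == length


class TestAverageSignal:
    def test_constant_interval_covering_bin(self, tiny_grid):
        track = average_signal([Interval("chr1", 0, 100, value=2.0)], tiny_grid)
        assert track.values[0] == pytest.approx(2.0)

    def test_half_covered_bin_dilutes_with_zeros(self, tiny_grid):
        track = average_signal([Interval("chr1", 0, 50, value=4.0)], tiny_grid)
        assert track.values[0] == pytest.approx(2.0)
        track2 = average_signal(
            [Interval("chr1", 0, 50, value=4.0)], tiny_grid, uncovered_as_zero=False
        )
        assert track2.values[0] == pytest.approx(4.0)

    def test_empty_input_gives_all_zero(self, tiny_grid):
        assert not average_signal([], tiny_grid).values.any()

    def test_out_of_bounds_interval_rejected(self, tiny_grid):
        with pytest.raises(InvalidInputError):
            average_signal([Interval("chr2", 500, 600, value=1.0)], tiny_grid)

    def test_matches_per_base_brute_force(self):
        """Oracle: per-base accumulation on random instances <= 10 kb."""
        rng = np.random.default_rng(0)
        genome = GenomeSpec(("chr1",), (10_000,))
        grid = make_bins(genome, 100)
        for _ in range(25):
            ivs = []
            for _ in range(rng.integers(1, 15)):
                s = int(rng.integers(0, 9_900))
                e = int(rng.integers(s + 1, min(10_000, s + 500)))
                ivs.append(Interval("chr1", s, e, value=float(rng.uniform(0, 5))))
            per_base = np.zeros(10_000)
            for iv in ivs:
                per_base[iv.start : iv.end] += iv.value
            expected = per_base.reshape(-1, 100).mean(axis=1)
            got = average_signal(ivs, grid).values
            np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestBinsOverlapping:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (150, 160, [1]),
            (95, 105, [0, 1]),
            (100, 200, [1]),
            (100, 201, [1, 2]),
            (0, 1000, list(range(10))),
        ],
    )
    def test_overlap_membership(self, tiny_grid, start, end, expected):
        got = bins_overlapping([Interval("chr1", start, end)], tiny_grid)
        assert got.tolist() == expected

    def test_peakset_input_and_empty(self, tiny_grid):
        ps = PeakSet("X", "CL", [Interval("chr2", 0, 50)])
        assert bins_overlapping(ps, tiny_grid).tolist() == [10]
        assert bins_overlapping([], tiny_grid).size == 0


class TestDistanceToFeatures:
    def test_edge_gap_conventions(self):
        anchors = [Interval("chr1", 200, 300)]
        queries = [
            Interval("chr1", 0, 100),    # gap 100
            Interval("chr1", 250, 260),  # overlap -> 0
            Interval("chr1", 100, 200),  # abutting -> 0
            Interval("chr1", 300, 400),  # abutting on the right -> 0
            Interval("chr2", 0, 100),    # no anchors on chr2 -> inf
        ]
        d = distance_to_features(queries, anchors)
        assert d.tolist() == [100.0, 0.0, 0.0, 0.0, np.inf]

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(InvalidInputError):
            distance_to_features([Interval("chr1", 0, 1)], [])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            anchors = [
                Interval("chr1", int(s), int(s) + int(rng.integers(1, 200)))
                for s in rng.integers(0, 9_000, size=8)
            ]
            queries = [
                Interval("chr1", int(s), int(s) + 50)
                for s in rng.integers(0, 9_000, size=10)
            ]
            got = distance_to_features(queries, anchors)
            for q, g in zip(queries, got):
                brute = min(
                    0 if (q.start < a.end and a.start < q.end)
                    else max(a.start - q.end, q.start - a.end)
                    for a in anchors
                )
                assert g == max(brute, 0)


class TestMergeIntervals:
    def test_gap_rules(self):
        a, b = Interval("chr1", 0, 100), Interval("chr1", 200, 300)
        assert merge_intervals([a, b], max_gap=100) == [Interval("chr1", 0, 300)]
        c = Interval("chr1", 250, 350)
        assert len(merge_intervals([a, c], max_gap=100)) == 2
        abut = [Interval("chr1", 0, 100), Interval("chr1", 100, 200)]
        assert merge_intervals(abut, max_gap=0) == [Interval("chr1", 0, 200)]

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 400)),
            min_size=1, max_size=20,
        ),
        st.integers(0, 150),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_merge_is_idempotent_and_gap_respecting(self, raw, max_gap):
        ivs = [Interval("chr1", s, s + l) for s, l in raw]
        merged = merge_intervals(ivs, max_gap)
        assert merge_intervals(merged, max_gap) == merged
        for x, y in zip(merged, merged[1:]):
            assert y.start - x.end > max_gap
        # union of bases is preserved (merging only bridges gaps)
        base = np.zeros(6000, dtype=bool)
        for iv in ivs:
            base[iv.start : iv.end] = True
        merged_mask = np.zeros(6000, dtype=bool)
        for iv in merged:
            merged_mask[iv.start : iv.end] = True
        assert (merged_mask & base).sum() == base.sum()


class TestIntersectSubtract:
    def test_against_base_mask_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            def rand_set():
                return [
                    Interval("chr1", int(s), int(s) + int(rng.integers(1, 300)))
                    for s in rng.integers(0, 4_000, size=6)
                ]
            A, B = rand_set(), rand_set()
            mask = np.zeros(5000, dtype=bool)
            for iv in A:
                mask[iv.start : iv.end] = True
            maskB = np.zeros(5000, dtype=bool)
            for iv in B:
                maskB[iv.start : iv.end] = True
            assert total_bases(intersect_intervals(A, B)) == int((mask & maskB).sum())
            assert total_bases(subtract_intervals(A, B)) == int((mask & ~maskB).sum())

    def test_normalize_merges_overlaps(self):
        ivs = [Interval("chr1", 0, 50), Interval("chr1", 25, 100)]
        assert normalize_intervals(ivs) == [Interval("chr1", 0, 100)]
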