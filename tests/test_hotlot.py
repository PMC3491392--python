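import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromclass.genome import BinGrid, GenomeSpec, Interval, PeakSet, SignalTrack
from chromclass.hotlot import (
    average_trf_tracks,
    block_overlap_z,
    call_hot_lot,
    cooccurrence_degree,
    discretize_track,
    estimate_cooccurrence_z,
    trf_weights,
    DegreeTrack,
)


@pytest.fixture
def grid():
    return BinGrid(GenomeSpec(("chr1",), (100_000,)), 100)


def track(grid, values):
    return SignalTrack(grid, np.asarray(values, float))


class TestAverageTracks:
    def test_replicate_mean_and_identity(self, grid):
        v1 = np.full(grid.n_bins, 2.0)
        v2 = np.full(grid.n_bins, 4.0)
        out = average_trf_tracks({"A": [track(grid, v1), track(grid, v2)],
                                  "B": [track(grid, v1)]})
        assert out["A"].values[0] == pytest.approx(3.0)
        np.testing.assert_array_equal(out["B"].values, v1)

    def test_zero_replicate_pulls_mean_down(self, grid):
        v = np.full(grid.n_bins, 3.0)
        z = np.zeros(grid.n_bins)
        out = average_trf_tracks({"A": [track(grid, v), track(grid, z), track(grid, z)]})
        assert out["A"].values[0] == pytest.approx(1.0)


class TestDiscretize:
    def test_all_zero_track_is_level_zero(self):
        d = discretize_track(np.zeros(50))
        assert not d.levels.any() and d.thresholds is None

    def test_octave_example_matches_nearest_rank_oracle(self):
        values = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 0], float)
        d = discretize_track(values)
        assert d.thresholds == (2.0, 4.0, 6.0)
        assert d.levels.tolist() == [0, 1, 1, 2, 2, 3, 3, 4, 4, 0]

    def test_identical_nonzero_values_fall_in_level_one(self):
        values = np.array([0, 7, 7, 7], float)
        d = discretize_track(values)
        assert d.levels.tolist() == [0, 1, 1, 1]

    @given(st.lists(st.integers(0, 40), min_size=4, max_size=60))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_levels_partition_nonzeros_by_brute_force_quartiles(self, raw):
        values = np.array(raw, float)
        d = discretize_track(values)
        nz = np.sort(values[values > 0])
        assert ((values == 0) == (d.levels == 0)).all()
        if len(nz) == 0:
            return
        # independent nearest-rank oracle
        def nr(p):
            return nz[max(1, int(np.ceil(p * len(nz)))) - 1]
        for v, lv in zip(values, d.levels):
            if v == 0:
                continue
            expected = 1 + (v > nr(0.25)) + (v > nr(0.5)) + (v > nr(0.75))
            assert lv == expected


class TestWeights:
    def make(self, raws):
        n = len(raws)
        M = np.zeros((n, n))
        for i in range(n):
            M[i, :] = raws[i]
            M[:, i] = raws[i]  # symmetric-ish; only row means matter
        for i in range(n):
            for j in range(n):
                if i != j:
                    M[i, j] = (raws[i] + raws[j]) / 2
        return pd.DataFrame(M, index=[f"T{i}" for i in range(n)],
                            columns=[f"T{i}" for i in range(n)])

    def test_two_trf_endpoint_mapping(self):
        Z = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        Z.loc["A", "B"] = 1.0
        Z.loc["B", "A"] = 5.0
        w = trf_weights(Z)
        np.testing.assert_allclose(w.raw, [1.0, 5.0])
        np.testing.assert_allclose(w.weights, [1.0, 0.5])

    def test_three_trf_linear_map(self):
        Z = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        Z.loc["A", ["B", "C"]] = [2.0, 2.0]
        Z.loc["B", ["A", "C"]] = [4.0, 4.0]
        Z.loc["C", ["A", "B"]] = [8.0, 8.0]
        w = trf_weights(Z)
        np.testing.assert_allclose(w.raw, [2.0, 4.0, 8.0])
        np.testing.assert_allclose(w.weights, [1.0, 1 - (2 / 6) * (2 / 3), 1 / 3])

    def test_degenerate_equal_raws_warn_uniform(self):
        Z = pd.DataFrame(np.ones((3, 3)), index=list("ABC"), columns=list("ABC"))
        with pytest.warns(UserWarning, match="equal"):
            w = trf_weights(Z)
        np.testing.assert_allclose(w.weights, 1.0)

    def test_endpoints_are_exact(self):
        rng = np.random.default_rng(0)
        n = 12
        M = rng.uniform(0, 30, (n, n))
        M = (M + M.T) / 2
        Z = pd.DataFrame(M, index=[f"T{i}" for i in range(n)],
                         columns=[f"T{i}" for i in range(n)])
        w = trf_weights(Z)
        assert w.weights[np.argmin(w.raw)] == pytest.approx(1.0)
        assert w.weights[np.argmax(w.raw)] == pytest.approx(1 / n)
        order = np.argsort(w.raw)
        assert (np.diff(w.weights[order]) <= 1e-12).all()  # monotone non-increasing


class TestDegree:
    def test_weighted_sum_example(self, grid):
        levels = {"A": np.zeros(grid.n_bins, np.int8),
                  "B": np.zeros(grid.n_bins, np.int8),
                  "C": np.zeros(grid.n_bins, np.int8)}
        levels["A"][0], levels["B"][0], levels["C"][0] = 4, 0, 2
        from chromclass.hotlot import TRFWeights
        w = TRFWeights(["A", "B", "C"], np.array([2.0, 4.0, 8.0]),
                       np.array([1.0, 0.7778, 1 / 3]))
        deg = cooccurrence_degree(levels, w, grid)
        assert deg.degrees[0] == pytest.approx(4 + 0 + 2 / 3, abs=1e-4)
        assert deg.degrees[1] == 0.0

    def test_matches_brute_force_on_random_bins(self, grid):
        """Oracle: per-bin Python-loop weighted sum on 1,000 random bins."""
        rng = np.random.default_rng(0)
        trfs = [f"T{i}" for i in range(6)]
        levels = {t: rng.integers(0, 5, grid.n_bins).astype(np.int8) for t in trfs}
        from chromclass.hotlot import TRFWeights
        wts = rng.uniform(1 / 6, 1, 6)
        w = TRFWeights(trfs, np.zeros(6), wts)
        deg = cooccurrence_degree(levels, w, grid)
        for b in rng.integers(0, grid.n_bins, 1000):
            expected = sum(wts[i] * levels[t][b] for i, t in enumerate(trfs))
            assert deg.degrees[b] == pytest.approx(expected, rel=1e-12)


class TestCallHotLot:
    def test_exact_counts_and_nonzero_lot_rule(self, grid):
        rng = np.random.default_rng(0)
        D = rng.uniform(0, 10, grid.n_bins)
        D[rng.choice(grid.n_bins, 400, replace=False)] = 0.0
        hot, lot = call_hot_lot(DegreeTrack(grid, D), pct=0.01)
        assert len(hot.bin_indices) == 10  # floor(0.01 * 1000)
        n_nz = int((D > 0).sum())
        assert len(lot.bin_indices) == int(np.floor(0.01 * n_nz))
        assert (D[lot.bin_indices] > 0).all()
        assert D[hot.bin_indices].min() >= D[lot.bin_indices].max()

    def test_all_equal_degrees_tie_rule_keeps_sets_disjoint(self, grid):
        D = np.ones(grid.n_bins)
        hot, lot = call_hot_lot(DegreeTrack(grid, D), pct=0.01)
        assert len(hot.bin_indices) == 10 and len(lot.bin_indices) == 10
        assert hot.bin_indices.tolist() == list(range(10))  # lowest index first
        assert not (hot.bin_index_set() & lot.bin_index_set())


class TestBlockZ:
    def domain(self):
        return [Interval("chr1", 0, 500_000)]

    def place(self, rng, n, L, length=500_000, chrom="chr1"):
        return [Interval(chrom, int(s), int(s) + L)
                for s in np.sort(rng.integers(0, length - L, n))]

    def test_identical_sets_give_large_positive_z(self):
        rng = np.random.default_rng(0)
        A = self.place(rng, 50, 300)
        res = block_overlap_z(A, A, self.domain(), n_samples=1000, seed=1)
        assert res.z > 5

    def test_degenerate_null_when_b_is_the_domain(self):
        rng = np.random.default_rng(0)
        A = self.place(rng, 20, 300)
        with pytest.raises(ValueError, match="degenerate"):
            block_overlap_z(A, self.domain(), self.domain(), n_samples=500, seed=0)

    def test_mutually_exclusive_sets_in_tight_domain_give_negative_z(self):
        # A fills the left half, B the right half of a small domain
        A = [Interval("chr1", 0, 40_000)]
        B = [Interval("chr1", 60_000, 100_000)]
        dom = [Interval("chr1", 0, 100_000)]
        res = block_overlap_z(A, B, dom, n_samples=1000, block_length=2000, seed=0)
        assert res.z < 0

    def test_z_invariant_to_chromosome_renaming(self):
        rng = np.random.default_rng(2)
        A = self.place(rng, 30, 200)
        B = self.place(rng, 40, 300)
        dom = self.domain()
        z1 = block_overlap_z(A, B, dom, n_samples=800, seed=5).z

        def ren(ivs):
            return [Interval("scaffold_9", iv.start, iv.end) for iv in ivs]

        z2 = block_overlap_z(ren(A), ren(B), ren(dom), n_samples=800, seed=5).z
        assert z1 == z2

    def test_cooccurrence_matrix_separates_planted_structure(self):
        """Identical sets give large z, independent sets small |z|."""
        rng = np.random.default_rng(3)
        shared = self.place(rng, 60, 300)
        sets = [
            PeakSet("A", "CL", shared),
            PeakSet("B", "CL", shared),
            PeakSet("C", "CL", self.place(rng, 60, 300)),
        ]
        Z = estimate_cooccurrence_z(sets, self.domain(), n_samples=500, seed=0)
        assert Z.loc["A", "B"] > 5
        assert Z.loc["A", "B"] > Z.loc["A", "C"]
        assert Z.loc["A", "C"] == Z.loc["C", "A"]  # symmetric storage
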