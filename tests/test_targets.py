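import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromclass.genome import Annotation, Interval, PeakSet, RegionSet, Transcript
from chromclass.synth import generate_pair_study
from chromclass.targets import (
    DRMModule,
    candidate_pairs,
    correlate_candidates,
    correlate_pair,
    ctcf_interposition,
    filter_module_marks,
    filter_transcripts,
    merge_drm_modules,
    pair_summaries,
    select_pairs,
)


def expr(rows: dict, assays=("polyA+ RNA-seq",), cells=None) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    cells = cells or [f"CL{i+1}" for i in range(n // len(assays))]
    cols = pd.MultiIndex.from_product([cells, list(assays)],
                                      names=["cell_line", "assay"])
    return pd.DataFrame([rows[t] for t in rows], index=list(rows), columns=cols,
                        dtype=float)


class TestMergeModules:
    def rs(self, ivs, cl):
        return RegionSet(kind="DRM", regions=list(ivs), cell_line=cl)

    def test_gap_of_100_merges_gap_of_101_does_not(self):
        a = self.rs([Interval("chr1", 0, 100)], "A")
        b = self.rs([Interval("chr1", 200, 300)], "B")
        mods = merge_drm_modules([a, b], max_gap=100)
        assert [(m.interval.start, m.interval.end) for m in mods] == [(0, 300)]
        c = self.rs([Interval("chr1", 201, 300)], "B")
        mods = merge_drm_modules([a, c], max_gap=100)
        assert len(mods) == 2

    def test_identical_bins_across_cell_lines_collapse(self):
        ivs = [Interval("chr1", 0, 100), Interval("chr1", 5000, 5100)]
        sets = [self.rs(ivs, cl) for cl in "ABC"]
        mods = merge_drm_modules(sets, max_gap=100)
        assert len(mods) == 2


class TestLevelFoldFilters:
    def test_transcript_rules(self):
        df = expr({
            "low": [1.5, 1.9],        # never reaches 2
            "flat": [5.0, 5.0],       # no two-fold difference
            "zero_min": [0.0, 4.0],   # zero minimum counts as infinite fold
            "good": [1.0, 4.0],
        })
        kept = filter_transcripts(df)
        assert kept == {"zero_min", "good"}

    def test_module_mark_rules(self):
        summaries = {
            "H3K4me1": pd.DataFrame(
                [[0.5, 1.0], [2.0, 2.0], [1.0, 4.0]],
                index=["M1", "M2", "M3"], columns=["CL1", "CL2"],
            )
        }
        elig = filter_module_marks(summaries)
        assert elig == {("M3", "H3K4me1")}


class TestCandidatePairs:
    def build(self, tss, n_cells=9, module_start=100_000):
        cells = [f"CL{i+1}" for i in range(n_cells)]
        mod = DRMModule("M0", Interval("chr1", module_start, module_start + 500))
        ann = Annotation([
            Transcript("T1", "G1", "chr1", "+", ((tss, tss + 1_000),)),
        ])
        summ = {"H3K4me1": pd.DataFrame([np.ones(n_cells)], index=["M0"],
                                        columns=cells)}
        e = expr({"T1": np.ones(n_cells)}, cells=cells)
        return [mod], ann, summ, e

    def test_distance_and_matched_cell_rules(self):
        mods, ann, summ, e = self.build(tss=600_000)
        assert len(candidate_pairs(mods, ann, summ, e)) == 1  # 0.5 Mbp away
        mods, ann, summ, e = self.build(tss=1_300_500)
        assert candidate_pairs(mods, ann, summ, e) == []  # > 1 Mbp
        mods, ann, summ, e = self.build(tss=600_000, n_cells=6)
        assert candidate_pairs(mods, ann, summ, e) == []  # 6 < 7 matched


class TestCorrelatePair:
    def test_zero_correlation_gives_p_one(self):
        x = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        y = np.array([1.0, 1.0, 2.0, 2.0, 1.0, 1.0])
        r, p = correlate_pair(x, y)
        assert r == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_fisher_oracle(self):
        """r = 0.99, n = 10: z = atanh(0.99) * sqrt(7) ~ 7.00, p ~ 2.4e-12."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = 0.8 * x + rng.normal(scale=0.5, size=n)
            r, p = correlate_pair(x, y)
            z = np.arctanh(r) * np.sqrt(n - 3)
            expected = 2.0 * 0.5 * __import__("math").erfc(abs(z) / np.sqrt(2))
            assert p == pytest.approx(expected, rel=1e-10)
        z99 = np.arctanh(0.99) * np.sqrt(7)
        assert z99 == pytest.approx(7.00, abs=0.01)
        p99 = 2 * stats.norm.sf(z99)
        assert p99 == pytest.approx(2.4e-12, rel=0.05)

    def test_degenerate_inputs_are_skipped(self):
        assert correlate_pair(np.ones(8), np.arange(8.0)) is None
        assert correlate_pair(np.arange(3.0), np.arange(3.0)) is None  # n < 4


class TestSelectPairs:
    def frame(self, ps, mark="H3K4me1", assay="a"):
        return pd.DataFrame({
            "module_id": [f"M{i}" for i in range(len(ps))],
            "transcript_id": [f"T{i}" for i in range(len(ps))],
            "mark": mark, "assay": assay, "n": 9, "r": 0.5, "p": ps,
            "distance": 1000,
        })

    def test_bonferroni_arithmetic(self):
        ps = [1e-8] + [0.5] * 9_999
        kept = select_pairs(self.frame(ps), alpha=0.01)
        assert len(kept) == 1 and kept.loc[0, "p_bonf"] == pytest.approx(1e-4)
        ps = [1e-5] + [0.5] * 9_999
        assert len(select_pairs(self.frame(ps), alpha=0.01)) == 0  # 0.1 > 0.01

    def test_single_test_reduces_to_alpha(self):
        assert len(select_pairs(self.frame([0.009]), alpha=0.01)) == 1
        assert len(select_pairs(self.frame([0.011]), alpha=0.01)) == 0

    def test_families_are_per_mark_assay_combination(self):
        a = self.frame([1e-4] * 10, mark="H3K4me1")
        b = self.frame([1e-4] * 1000, mark="H3K27ac")
        both = pd.concat([a, b], ignore_index=True)
        kept = select_pairs(both, alpha=0.01)
        # 1e-4 * 10 = 1e-3 < 0.01 kept; 1e-4 * 1000 = 0.1 rejected
        assert set(kept["mark"]) == {"H3K4me1"}
        kept_global = select_pairs(both, alpha=0.01, family="global")
        assert len(kept_global) == 0


class TestCtcfInterposition:
    def test_between_rule(self):
        mods = [DRMModule("M0", Interval("chr1", 10_000, 10_500))]
        ann = Annotation([Transcript("T1", "G1", "chr1", "+", ((50_000, 51_000),))])
        pairs = pd.DataFrame({
            "module_id": ["M0"], "transcript_id": ["T1"],
            "mark": ["m"], "assay": ["a"], "n": [9], "r": [0.9], "p": [1e-9],
            "distance": [39_500],
        })
        assert ctcf_interposition(pairs, mods, ann, [Interval("chr1", 30_000, 30_200)]) == 1.0
        assert ctcf_interposition(pairs, mods, ann, [Interval("chr1", 5_000, 5_200)]) == 0.0
        # peak overlapping the open interval boundary does not count when the
        # between-interval is empty (module abutting the TSS)
        mods2 = [DRMModule("M0", Interval("chr1", 49_000, 50_000))]
        assert ctcf_interposition(pairs, mods2, ann, [Interval("chr1", 30_000, 30_200)]) == 0.0


def test_pair_summaries_single_pair_unit_masses():
    pairs = pd.DataFrame({
        "module_id": ["M0", "M0", "M1"], "transcript_id": ["T1", "T2", "T1"],
        "mark": ["m", "m", "m"], "assay": ["a", "a", "a"], "n": 9, "r": 0.9,
        "p": 1e-9, "distance": [50_000, 150_000, 950_000],
    })
    s = pair_summaries(pairs)
    assert s["transcripts_per_module"]["M0"] == 2
    assert s["modules_per_transcript"]["T1"] == 2
    assert s["pairs_per_mark"]["m"] == 3
    hist = s["distance_hist"]["a"]
    assert len(hist) == 10 and hist[0] == 1 and hist[1] == 1 and hist[9] == 1


def test_bonferroni_is_conservative_under_global_null():
    """With valid per-test p-values (exact Pearson null: r^2 ~
    Beta(1/2, (n-2)/2)), Bonferroni yields at most alpha expected
    discoveries per family; the Fisher-transform p the pipeline uses is
    mildly anti-conservative in its far tail at n = 9, so its spurious
    selections are bounded at their analytically expected rarity instead."""
    total_fisher = 0
    total_exact = 0
    for seed in range(10):
        modules, msum, ann, e, planted = generate_pair_study(
            seed=seed, n_modules=60, n_transcripts=40, n_planted=0,
            chrom_length=3_000_000,
        )
        mods = [DRMModule(f"M{i:06d}", iv) for i, iv in enumerate(modules)]
        summ = {"H3K4me1": msum.set_axis([m.module_id for m in mods], axis=0)}
        cands = candidate_pairs(mods, ann, summ, e, min_matched_cells=7)
        tested = correlate_candidates(cands, summ, e)
        total_fisher += len(select_pairs(tested, alpha=0.01))
        p_exact = stats.beta.sf(tested["r"] ** 2, 0.5, (tested["n"] - 2) / 2)
        total_exact += int((p_exact * len(tested) < 0.01).sum())
    assert total_exact <= 1
    assert total_fisher <= 6
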