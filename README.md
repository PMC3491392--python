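# chromclass

Supervised classification of human genomic regions from binned chromatin
features, rebuilt as a tested, reusable pipeline and exercised end to end on
synthetic multi-cell-line data with planted ground truth.

The package is aimed at computational/regulatory genomicists who want the
six-region analysis — binding-active/inactive regions, promoter-proximal and
gene-distal regulatory modules, HOT/LOT regions — as composable, unit-tested
Python functions rather than a one-off analysis: every statistic is exposed
on its own, and a synthetic-data generator provides planted truth so each
stage's recovery can be measured.

## What it computes

The genome is tiled into 100 bp bins; each assay (DNase, FAIRE, histone
marks, TRF ChIP-seq) becomes a per-bin mean-signal vector. On top of this
grid the pipeline calls six region types per cell line:

- **BAR / BIR** (binding-active / binding-inactive regions): a random-forest
  classifier is trained on chromatin features of TRF-peak-overlapping bins
  (5,000 positives vs 5,000 random negatives) under 10-fold
  cross-validation; every bin receives the mean score of the ten fold
  models. BARs are bins with score > 0.9; BIRs have score < 0.1 and overlap
  no peak.
- **PRM / DRM** (promoter-proximal / gene-distal regulatory modules): the
  same machinery with positives at TSS bins of expressed transcripts
  (RPKM ≥ 1 or CAGE/diTag RPM ≥ 1) and a composite negative set; the PRM
  threshold is the score with exactly 1% of held-out negatives above it,
  averaged over folds. DRMs are non-PRM BAR bins ≥ 10 kbp from any gene.
- **HOT / LOT**: each TRF's averaged binding track is discretized into five
  levels (0 = zero signal; nonzero quartiles coded 1–4) and each TRF gets a
  weight from its global co-occurrence z with all other TRFs — the least
  co-associating TRF gets weight 1, the most gets 1/n, linear in between.
  The degree of region-specific co-occurrence of a bin is
  `D_b = Σ_t w_t · level_{t,b}`; HOT regions are the top 1% of bins by
  degree, LOT regions the bottom 1% of nonzero-degree bins.
- **Enhancer candidates**: two rounds of auditable filter chains
  (TSS/exon exclusion, conservation, size, motif density; then a two-stage
  window/profile classifier intersected with a BAR filter chain and refined
  to 100–700 bp fragments with median H3K4me1 or H3K4me3 > 5).
- **DRM–target association**: DRM bins from all cell lines are merged into
  modules (100 bp gaps allowed); module mark signal is correlated with
  transcript expression across cell lines (same chromosome, ≤ 1 Mbp,
  ≥ 7 matched cell lines). Significance uses the Fisher transformation,
  `z = atanh(r)·√(n−3)`, with Bonferroni control at 0.01 per
  (mark, assay) family.
- **Motifless-peak / HOT overlap**: peaks lacking any known or novel motif
  of their own TRF are intersected with HOT regions inside peak space; the
  overlap's significance comes from block sampling within the peak-set
  domain, a Gaussian fitted to the null ratios, and a z-score whose p-value
  is computed in log space (the tail at z = 25 is ~3 × 10⁻¹³⁸).

## Worked example

```python
from chromclass.synth import SynthConfig, generate_dataset, truth_eval
from chromclass.pipeline import (PipelineConfig, stage_bar_bir,
                                 stage_cooccurrence, stage_hot_lot)

synth = dict(n_chroms=1, chrom_length=1_500_000, n_cell_lines=3, n_trfs=10,
             n_active_loci=60, n_distal_loci=15, n_hot_loci=10,
             block_sizes=(3,), n_private_loci=25, n_couplings=8)
cfg = PipelineConfig(seed=7, synth=synth, n_pos=1500, n_neg=1500,
                     n_trees=60, coocc_n_samples=300)
ds = generate_dataset(cfg.synth_config())

bb = stage_bar_bir(ds, cfg, "CL1")
pr = truth_eval(bb["bars"], ds.truth.active_loci["CL1"])
print(f"BAR calling:  cross-validated AUROC = {bb['cv'].mean_auroc:.3f}")
print(f"              {len(bb['bars'])} regions, base precision = "
      f"{pr.base_precision:.2f}, base recall = {pr.base_recall:.2f}")

Z = stage_cooccurrence(ds, cfg, "CL1")
hl = stage_hot_lot(ds, cfg, "CL1", Z)
hot_pr = truth_eval(hl["hot"], ds.truth.hot_loci["CL1"])
w = hl["weights"]
print(f"HOT calling:  {len(hl['hot'])} regions, planted-locus recall = "
      f"{hot_pr.element_recall:.2f}")
print(f"              TRF weights span [{w.weights.min():.2f}, "
      f"{w.weights.max():.2f}] (block TRFs down-weighted)")
```

prints

```
BAR calling:  cross-validated AUROC = 0.836
              426 regions, base precision = 0.99, base recall = 0.77
HOT calling:  86 regions, planted-locus recall = 1.00
              TRF weights span [0.10, 1.00] (block TRFs down-weighted)
```

On this deliberately small 1.5 Mbp example the classifier separates bound
from unbound bins with AUROC 0.84 and the regions it calls are almost pure
(99% of called bases lie in planted active loci) while recovering 77% of
the planted bases; every planted many-TRF locus lands in the top-1% degree
bins, and the five co-associating block TRFs receive the smallest weights.
At the default study scale (10 Mbp, 5 cell lines, 20 TRFs) the same numbers
rise to AUROC ≈ 0.94 with ≈ 86% base recall at ≈ 98% precision.

The same stages are available from the shell:

```bash
chromclass run-all --seed 7 --outdir run/          # everything, all outputs
chromclass simulate --seed 7 --outdir data/        # just the dataset
chromclass call-bar-bir --seed 7 --outdir run/ --cell-line CL1
```

Every `run-all` output directory contains a `manifest.json` with SHA-256
checksums of all outputs; two runs with the same master seed are
byte-identical.

## Layout

| module | contents |
|---|---|
| `chromclass.genome` | genome model, bin grid, interval algebra, region sets |
| `chromclass.io` | BED/narrowPeak/bedGraph/wiggle/GTF/expression readers & writers |
| `chromclass.synth` | synthetic dataset generator with planted truth |
| `chromclass.barbir` | classifier contract, cross-validation, BAR/BIR calling |
| `chromclass.prmdrm` | expressed-TSS positives, negative subsets, PRM/DRM calling |
| `chromclass.hotlot` | discretization, TRF weights, degree, HOT/LOT, block bootstrap |
| `chromclass.enhancers` | round-1/round-2 filter chains and boundary refinement |
| `chromclass.targets` | DRM modules, filters, correlation, Bonferroni, CTCF statistics |
| `chromclass.motifless` | motifless peaks, intergenic restriction, overlap z |
| `chromclass.reporting` | distribution summaries, sharing, peak-in-region fractions |
| `chromclass.pipeline` / `chromclass.cli` | orchestration and the `chromclass` command |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
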