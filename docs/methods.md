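# Methods

This note records the models, conventions and design choices behind the
pipeline, in the order the stages run. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate model

All coordinates are 0-based half-open; 1-based formats (GTF, wiggle) are
converted at the I/O boundary. The genome is tiled into fixed-width bins
(default 100 bp); the trailing bin of a chromosome may be shorter and is
kept, with region size accounting using true base lengths. Bases not
covered by any signal interval contribute 0 to a bin's mean (dense signal
files; absence = no enrichment), with a flag to average over covered bases
only. Abutting intervals (end == start) have distance 0. Strand is ignored
for bin/peak arithmetic and used only to orient TSSs and their flanking
windows. Quantiles everywhere are nearest-rank (the smallest value with at
least the requested fraction at or below it) so results are reproducible
bit for bit across platforms.

## Synthetic data

The generator emulates the inputs of the analysis at desk scale. Defaults:
2 chromosomes × 5 Mbp, 100 bp bins, 5 cell lines, 20 TRFs (the first two
named POL2RA and CTCF, which get promoter-biased and scattered binding
respectively), and 7 chromatin features (DNase, FAIRE, H3K4me1, H3K4me3,
H3K27ac, H3K36me3, H3K27me3).

**Signal model.** Per-bin background is independent log-normal
(median 1, log-sd 0.5). Enrichment at a planted locus is a plateau of a
per-(category, feature) amplitude with 150 bp linear ramps outside, scaled
by a per-cell-line factor. A plateau rather than a triangle is used so the
planted extent is recoverable by a bin classifier; the amplitudes
(e.g. DNase 5–9, H3K4me3 9 at promoters, H3K4me1 9 at distal loci) are
several background standard deviations, i.e. clearly "informative
features". H3K4me1 amplitudes are graded (distal 9 > hot 3.5 > generic
active 2.5) so that the median-signal > 5 rule used in enhancer refinement
separates the planted enhancer class.

**Planted loci.** Four categories per cell line: generic active loci,
promoter loci (±500 bp around TSSs of expressed genes), distal loci
(placed ≥ 12 kb from any gene, conserved, motif-rich, strongly
H3K4me1-marked), and HOT loci. In addition every TRF has its own private
loci placed genome-wide. All loci are placed without stacking (a
bin-resolution occupancy mask) and snapped to bin boundaries: the callers
operate at bin granularity, and unaligned truth would penalize base-level
recall for purely geometric reasons unrelated to the method.

**Binding model.** Two blocks of five TRFs co-associate globally: block
members bind shared block loci, and co-binding peaks at a block or HOT
locus share an anchored site (±50 bp jitter) — co-association means
binding the same sites, not merely the same neighbourhoods. Each TRF also
binds its private loci and a few shared ones. At each HOT locus, 8–16 TRFs
drawn across blocks and singletons bind with elevated signal. TRF signal
tracks are sparse (zeros outside peaks plus 8% exponential noise bins),
matching the zero-inflated character of ChIP-seq binding signal that the
five-level discretization expects.

**Motifs and expression.** Each peak carries a motif of its TRF with
probability 0.8, halved (0.4) at HOT loci; sites are split between "known"
and "novel" catalogs and a small number of background sites are scattered
genome-wide. Expression tables cover five assay types; a transcript of an
expressed gene draws log-normal positive values. A configurable number of
distal modules are coupled to nearby transcripts: the transcript's
expression across cell lines is an affine function of the module's
realized H3K4me1 signal plus Gaussian noise calibrated so the population
correlation equals the configured ρ (0.9 by default in the full dataset).

**What the generator does not emulate:** read-level sequencing noise,
mappability and copy-number artifacts, correlated background along the
genome, realistic motif sequence models (sites are intervals, not PWM
matches), unannotated transcription, and TRFs missing in some cell lines.
Passing tests therefore show that the statistics recover the structure
they are defined on when that structure is present — not that they are
robust to every artifact of real ENCODE tracks.

## BAR/BIR and PRM/DRM calling

The classifier contract is fit/score with scores in [0, 1]; the default is
a 100-tree random forest (seeded, single-threaded). Fold assignment is
stratified and seeded. The genome score of a bin is the mean over all k
fold models, matching the "average score from the ten folds" rule — this
includes, for a training bin, folds where it was a training example; a
strict out-of-fold variant is available. Scores are rounded to 3 decimals
before thresholding so the strict > 0.9 / < 0.1 boundaries are
platform-stable. BAR and BIR are mutually exclusive by construction.

PRM negatives are sampled in equal thirds from (1) bins without any TRF
binding, (2) non-POL2RA peak bins ≥ 10 kb from any gene (gene = union span
of its transcripts), and (3) peak-free bins 1–5 kb upstream or 0.2–1 kb
downstream of a TSS, strand-aware. The PRM threshold is computed per fold
on that fold's held-out negatives — the smallest observed score with
exactly ⌊0.01·N⌋ negatives strictly above it, ties resolving toward fewer
— and averaged over folds (a pooled variant exists). DRMs are non-PRM BAR
bins ≥ 10 kbp from any gene span.

## HOT/LOT

Replicate tracks per TRF are averaged; nonzero values are split at the
nearest-rank 25/50/75 percentiles into levels 1–4 (zeros are level 0;
values equal to a threshold fall in the lower level; all-equal nonzero
values land in level 1). Levels enter the degree as integers 0–4 — the
categories need a numeric code and a monotone integer coding is the
minimal choice; it is configurable. The TRF weight map sends the lowest
mean off-diagonal co-occurrence z to 1 and the highest to 1/n linearly;
the diagonal is excluded (self co-occurrence is uninformative); if all raw
scores tie, weights are uniform with a warning.

HOT is the top ⌊pct·N⌋ of all bins by degree (ties broken toward the
lowest bin index); LOT is the bottom ⌊pct·N_nz⌋ of the bins with nonzero
degree, excluding any bin already selected as HOT — under massive degree
ties the plain tie rule would select the same bins for both, and the sets
are kept disjoint by construction.

The co-occurrence z matrix may be supplied or estimated by a fixed-length
block bootstrap: one peak set's base mass is re-placed as uniform blocks
(default length 10× its mean peak length) within the domain, the base
overlap ratio with the other set recorded, and the observed ratio
standardized by the null sample moments. This is a deliberate, documented
simplification of segment-structure-preserving overlap correction; the
full framework is out of scope. The pipeline estimates the matrix per
cell line from that cell line's peaks, which matches the per-cell-line n
in the weighting rule.

## Enhancer prediction

Round 1 (conservation/motif ranking) applies, in order: strand-aware
TSS-flank exclusion (2 kb up / 500 bp down), exon ±1 kb exclusion, top 2%
of surviving bins by conservation, merge, size filter 0.8–4 kb, and
ranking by motif density (count/length, top 50). At the 10 Mbp study scale
the verbatim top-2% rule leaves ~120 bins, which rarely form ≥ 800 bp
runs, so round 1 returns few or no candidates there; this is the honest
desk-scale behaviour of the rule and the chain is validated on controlled
fixtures.

Round 2 intersects two candidate lists. Method 1 filters BAR bins
(promoter score > 0.8, TSS ± 2 kb, exon overlap, conservation < 0.1
removed; merged regions must contain a motif of an expressed TRF). Method
2 is a two-stage predictor: stage 1 scores 1 kb windows on aggregate
(mean) feature values, trained peak-windows vs random windows; stage 2
re-scores survivors on the signal profile across ten 100 bp sub-bins,
trained peak-centred windows vs 1 kb-offset flanks. Candidate windows are
re-centred on their strongest sub-bin before profiling so candidate and
training profiles align. Survivors pass repeat removal, exon/TSS ± 2 kb
filters, and must involve H3K4me1 or H3K4me3 (window mean above a
configurable floor, default 2). Stage cutoffs (0.5/0.5), the repeat list
and the involvement floor are named config parameters: this stage is a
faithful reconstruction of an under-specified procedure, not a
replication. The intersection is refined to fragments of 100–700 bp
(long fragments trimmed symmetrically about the H3K4me1+H3K4me3-weighted
centre) and kept if the per-base median H3K4me1 or H3K4me3 exceeds 5
(strict).

## DRM–target association

DRM bins from all cell lines are merged with 100 bp gaps into modules.
Module mark summary = mean over member bins (max available by config).
Transcripts need a value ≥ 2 in some cell line and ≥ 2-fold variation
(a zero minimum counts as infinite fold); module marks analogously.
Candidates are same-chromosome pairs with TSS within 1 Mbp of the nearest
module edge (TSS anchoring is the regulatory reading of "apart";
body-anchoring is configurable) and ≥ 7 matched cell lines (cell lines
with both values present). Pearson r is tested via the Fisher
transformation, z = atanh(r)·√(n−3), two-sided normal tail; Bonferroni
control is per (mark, assay) family by default, with a global option.

**Known limitation.** The Fisher normal approximation is anti-conservative
in its far tail at small n: at n = 9 the exceedance of p ≈ 2 × 10⁻⁶ is
~20× nominal even for exactly normal data (the exact null is
r² ~ Beta(1/2, (n−2)/2)). Consequently, Bonferroni's ≤ α expected null
discoveries holds for exact p-values but not strictly for the
Fisher-approximate ones that the method uses; with ~5,000-pair families at
α = 0.01 the expected spurious selections are ~0.2 per family — still
rare, and the planted-coupling precision stays ≥ 0.9. The test suite
verifies both facts separately.

CTCF interposition counts pairs with ≥ 1 CTCF peak strictly inside the
open interval between the nearest module edge and the TSS. Distance
histograms use fixed 100 kb bins to 1 Mbp.

## Motifless peaks and overlap significance

A peak is motifless iff it contains neither a known nor a novel motif of
its own TRF (other TRFs' motifs are allowed); the cell-line set is the
union over TRFs. HOT regions are first clipped to peak space, then their
overlap with motifless peaks is tested by block sampling within the
whole-peak-set domain: the HOT-in-peaks set is the one re-placed (holding
the motifless set fixed; a symmetric option exists), the null ratios are
summarized by their sample mean and sd, and p-values from z are computed
in log space, which keeps them finite beyond the double-precision
underflow at z ≈ 38. The intergenic variant first restricts every set to
bases ≥ 10 kb from any gene span, clipping at the boundary. A degenerate
null (zero variance, e.g. the fixed set covering the domain) is an error,
not a silent zero.

## Reporting

Box-plot summaries use nearest-rank quartiles computed before trimming;
values outside [Q1 − 5·IQR, Q3 + 5·IQR] are excluded from whiskers and the
mean. One-pass trimming is a fixed point for the moderately tailed
distributions it is applied to; for extremely heavy tails the recomputed
quartiles of the trimmed data can shift, and the method deliberately trims
once. Sharing statistics are computed over the union of covered bins and
sum to 1 both by count and by cell-line combination. A peak is "within" a
region type if ≥ 50% of its bases overlap it (configurable to
any-overlap).

## Problem sizes and determinism

The default study conditions are 5 cell lines × 10 Mbp × 20 TRFs
(100,000 bins), with 5,000/5,000 training bins, 10 folds and 100 trees;
the coupling-recovery study uses 9 cell lines, 250 modules and 105
transcripts (~5,000 candidate pairs, 50 planted couplings at ρ ≈ 0.98);
block-sampling uses 10,000 null samples for reported z-scores and 2,000
for calibration sweeps. The end-to-end determinism check runs the full
pipeline twice at a reduced size (1 × 1.5 Mbp, 4 cell lines, 10 TRFs,
60 trees) — determinism is scale-invariant, and this keeps the check
inexpensive. Every stage derives its seed from the master seed by fixed
arithmetic, random forests are seeded and single-threaded, and all outputs
are plain text with fixed float formatting, so two runs with one master
seed are byte-identical (verified by SHA-256 in the run manifest).
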