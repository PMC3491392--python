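"""End-to-end orchestration: simulate -> BAR/BIR -> PRM/DRM -> HOT/LOT ->
enhancers -> DRM-target pairs -> motifless overlap -> reports.

Every stage is seeded from the master seed, logs its parameters, and writes
plain-text outputs (BED/bedGraph/TSV/JSON); a manifest with SHA-256
checksums of all outputs makes determinism checkable byte for byte.  The
per-stage functions are also the backend of the CLI subcommands, which can
re-run any stage from prior outputs on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import barbir, enhancers, hotlot, io as cio, motifless, prmdrm, reporting, targets
from .genome import Interval, RegionSet, normalize_intervals
from .synth import SynthConfig, SynthDataset, generate_dataset, truth_eval

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Master configuration; every stage draws its seed from ``seed``."""

    seed: int = 0
    synth: dict = field(default_factory=dict)  # overrides for SynthConfig
    # BAR/BIR
    n_pos: int = 5000
    n_neg: int = 5000
    k_folds: int = 10
    n_trees: int = 100
    bar_threshold: float = 0.9
    bir_threshold: float = 0.1
    # PRM/DRM
    prm_negative_fraction: float = 0.01
    rpkm_min: float = 1.0
    rpm_min: float = 1.0
    gene_min_dist: int = 10_000
    # HOT/LOT
    hot_pct: float = 0.01
    coocc_n_samples: int = 500
    # enhancers
    enhancer_top_k: int = 50
    # pairs
    pair_min_matched_cells: int = 5
    pair_alpha: float = 0.01
    pair_max_dist: int = 1_000_000
    # motifless
    motifless_n_samples: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "synth" in data and data["synth"]:
            synth_known = {f.name for f in dataclasses.fields(SynthConfig)}
            bad = set(data["synth"]) - synth_known
            if bad:
                raise ValueError(f"unknown synth config key(s): {', '.join(sorted(bad))}")
        return cls(**data)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(**{"seed": self.seed, **self.synth})


def _seed(master: int, stage: int, sub: int = 0) -> int:
    """Derived stage seed, stable and below 2**31."""
    return (master * 10_007 + stage * 101 + sub) % (2**31 - 1)


# -- stages -----------------------------------------------------------------


def stage_bar_bir(ds: SynthDataset, cfg: PipelineConfig, cell_line: str):
    grid = ds.grid
    tracks = [ds.feature_tracks[cell_line][m] for m in ds.config.marks]
    X = barbir.feature_matrix(tracks)
    peaksets = ds.all_peaks(cell_line)
    ci = ds.cell_lines.index(cell_line)
    pos, neg = barbir.sample_training_bins(
        grid, peaksets, cfg.n_pos, cfg.n_neg, seed=_seed(cfg.seed, 1, ci)
    )
    cv = barbir.crossval_train_score(
        X, grid, pos, neg, k=cfg.k_folds,
        classifier=barbir.ForestBinClassifier(n_estimators=cfg.n_trees),
        seed=_seed(cfg.seed, 2, ci), kind="BAR", cell_line=cell_line,
    )
    bars = barbir.call_bars(cv.score_track, cfg.bar_threshold)
    birs = barbir.call_birs(cv.score_track, peaksets, cfg.bir_threshold)
    logger.info(
        "BAR/BIR %s: AUROC=%.3f AUPR=%.3f bars=%d birs=%d",
        cell_line, cv.mean_auroc, cv.mean_aupr, len(bars), len(birs),
    )
    return {"cv": cv, "bars": bars, "birs": birs}


def stage_prm_drm(ds: SynthDataset, cfg: PipelineConfig, cell_line: str, bars: RegionSet):
    grid = ds.grid
    tracks = [ds.feature_tracks[cell_line][m] for m in ds.config.marks]
    X = barbir.feature_matrix(tracks)
    peaksets = ds.all_peaks(cell_line)
    ci = ds.cell_lines.index(cell_line)
    pos = prmdrm.expressed_tss_bins(
        ds.annotation, ds.expression, grid, cell_line, cfg.rpkm_min, cfg.rpm_min
    )
    negs = prmdrm.prm_negative_bins(
        grid, peaksets, ds.annotation, n_neg=cfg.n_neg,
        min_gene_dist=cfg.gene_min_dist, seed=_seed(cfg.seed, 3, ci),
    )
    cv = barbir.crossval_train_score(
        X, grid, pos, negs.concatenated(), k=cfg.k_folds,
        classifier=barbir.ForestBinClassifier(n_estimators=cfg.n_trees),
        seed=_seed(cfg.seed, 4, ci), kind="PRM", cell_line=cell_line,
    )
    thr = prmdrm.prm_threshold(cv.fold_negative_scores, cfg.prm_negative_fraction)
    prms = prmdrm.call_prms(cv.score_track, thr)
    drms = prmdrm.call_drms(bars, prms, ds.annotation, cfg.gene_min_dist)
    logger.info(
        "PRM/DRM %s: AUROC=%.3f threshold=%.3f prms=%d drms=%d",
        cell_line, cv.mean_auroc, thr, len(prms), len(drms),
    )
    return {"cv": cv, "threshold": thr, "prms": prms, "drms": drms}


def stage_cooccurrence(ds: SynthDataset, cfg: PipelineConfig, cell_line: str) -> pd.DataFrame:
    """Genome-wide co-occurrence z matrix of one cell line's peak sets."""
    ci = ds.cell_lines.index(cell_line)
    sets = [ds.peaksets[cell_line][trf] for trf in ds.trf_names]
    domain = [
        Interval(c, 0, l)
        for c, l in zip(ds.genome.chrom_names, ds.genome.chrom_lengths)
    ]
    return hotlot.estimate_cooccurrence_z(
        sets, domain, n_samples=cfg.coocc_n_samples, seed=_seed(cfg.seed, 5, ci)
    )


def stage_hot_lot(ds: SynthDataset, cfg: PipelineConfig, cell_line: str, coocc: pd.DataFrame):
    deg, weights, _ = hotlot.region_cooccurrence_degrees(
        ds.trf_tracks[cell_line], coocc, ds.grid, cell_line=cell_line
    )
    hot, lot = hotlot.call_hot_lot(deg, pct=cfg.hot_pct)
    logger.info("HOT/LOT %s: hot=%d lot=%d", cell_line, len(hot), len(lot))
    return {"degrees": deg, "weights": weights, "hot": hot, "lot": lot}


def stage_enhancers(ds: SynthDataset, cfg: PipelineConfig, cell_line: str,
                    bars: RegionSet, prm_scores):
    r1, rep1 = enhancers.round1_candidates(
        bars, ds.annotation, ds.conservation, ds.motif_sites_known,
        top_k=cfg.enhancer_top_k,
    )
    m1, repm1 = enhancers.round2_method1(
        bars, prm_scores, ds.annotation, ds.conservation, ds.motif_sites_known
    )
    tracks = [ds.feature_tracks[cell_line][m] for m in ds.config.marks]
    m2, repm2 = enhancers.round2_method2(
        tracks, ds.all_peaks(cell_line), ds.annotation, ds.grid,
        repeats=ds.repeats, seed=_seed(cfg.seed, 6), cell_line=cell_line,
    )
    final, repf = enhancers.combine_and_refine(
        m1, m2,
        ds.feature_tracks[cell_line]["H3K4me1"],
        ds.feature_tracks[cell_line]["H3K4me3"],
    )
    logger.info(
        "enhancers %s: round1=%d m1=%d m2=%d final=%d",
        cell_line, len(r1), len(m1), len(m2), len(final),
    )
    return {
        "round1": r1, "method1": m1, "method2": m2, "final": final,
        "reports": {"round1": rep1, "method1": repm1, "method2": repm2, "refine": repf},
    }


def stage_pairs(ds: SynthDataset, cfg: PipelineConfig, drms_by_cell: dict[str, RegionSet]):
    modules = targets.merge_drm_modules(list(drms_by_cell.values()), max_gap=100)
    mark_tracks = {
        cl: {m: ds.feature_tracks[cl][m] for m in ds.config.marks if m.startswith("H3")}
        for cl in ds.cell_lines
    }
    summaries = targets.module_mark_summaries(modules, mark_tracks)
    elig_t = targets.filter_transcripts(ds.expression, per_assay=True)
    elig_m = targets.filter_module_marks(summaries)
    cands = targets.candidate_pairs(
        modules, ds.annotation, summaries, ds.expression,
        eligible_transcripts=elig_t, eligible_module_marks=elig_m,
        max_dist=cfg.pair_max_dist, min_matched_cells=cfg.pair_min_matched_cells,
    )
    tested = targets.correlate_candidates(cands, summaries, ds.expression)
    selected = targets.select_pairs(tested, alpha=cfg.pair_alpha)
    selected = targets.associate_trfs(selected, modules, ds.peaksets, summaries)
    ctcf = [p for cl in ds.cell_lines for p in ds.peaksets[cl]["CTCF"].peaks] \
        if "CTCF" in ds.trf_names else []
    frac_ctcf = (
        targets.ctcf_interposition(selected, modules, ds.annotation, ctcf)
        if len(selected) and ctcf else float("nan")
    )
    logger.info("pairs: candidates=%d tested=%d selected=%d", len(cands), len(tested), len(selected))
    return {
        "modules": modules, "summaries": summaries, "tested": tested,
        "selected": selected, "ctcf_fraction": frac_ctcf,
    }


def stage_motifless(ds: SynthDataset, cfg: PipelineConfig, hot_by_cell: dict[str, RegionSet]):
    return motifless.motifless_hot_table(
        ds.peaksets, hot_by_cell, ds.motif_sites_known, ds.motif_sites_novel,
        annotation=ds.annotation, n_samples=cfg.motifless_n_samples,
        seed=_seed(cfg.seed, 7),
    )


# -- orchestration ----------------------------------------------------------


def _write_regions(rs: RegionSet, path: Path) -> None:
    cio.write_bed(rs.regions, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on the synthetic dataset and write all outputs.

    Returns a manifest dict (parameters, per-stage summaries, output
    checksums) that is also written to ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config.synth_config())
    cio.write_chrom_sizes(ds.genome, out / "chrom.sizes")
    cio.write_gtf(ds.annotation, out / "annotation.gtf")
    (out / "truth.json").write_text(ds.truth.to_json())

    summaries: dict = {"seed": config.seed, "cell_lines": ds.cell_lines}
    bars_by_cell, drms_by_cell, hot_by_cell = {}, {}, {}
    prm_scores = {}
    region_sets_by_type: dict[str, dict[str, RegionSet]] = {
        k: {} for k in ("BAR", "BIR", "PRM", "DRM", "HOT", "LOT")
    }
    for cl in ds.cell_lines:
        cdir = out / cl
        cdir.mkdir(exist_ok=True)
        bb = stage_bar_bir(ds, config, cl)
        pd_ = stage_prm_drm(ds, config, cl, bb["bars"])
        coocc = stage_cooccurrence(ds, config, cl)
        coocc.to_csv(cdir / "cooccurrence_z.tsv", sep="\t", float_format="%.6g")
        hl = stage_hot_lot(ds, config, cl, coocc)
        bars_by_cell[cl] = bb["bars"]
        drms_by_cell[cl] = pd_["drms"]
        hot_by_cell[cl] = hl["hot"]
        prm_scores[cl] = pd_["cv"].score_track
        for name, rs in (
            ("bars", bb["bars"]), ("birs", bb["birs"]), ("prms", pd_["prms"]),
            ("drms", pd_["drms"]), ("hot", hl["hot"]), ("lot", hl["lot"]),
        ):
            _write_regions(rs, cdir / f"{name}.bed")
        region_sets_by_type["BAR"][cl] = bb["bars"]
        region_sets_by_type["BIR"][cl] = bb["birs"]
        region_sets_by_type["PRM"][cl] = pd_["prms"]
        region_sets_by_type["DRM"][cl] = pd_["drms"]
        region_sets_by_type["HOT"][cl] = hl["hot"]
        region_sets_by_type["LOT"][cl] = hl["lot"]
        cio.write_track_bedgraph(
            hotlot.SignalTrack(ds.grid, hl["degrees"].degrees, assay="degree", cell_line=cl),
            cdir / "degrees.bedGraph",
        )
        pd.DataFrame(
            {"trf": hl["weights"].trfs, "raw": hl["weights"].raw, "weight": hl["weights"].weights}
        ).to_csv(cdir / "weights.tsv", sep="\t", index=False, float_format="%.6g")
        summaries[cl] = {
            "bar_auroc": bb["cv"].mean_auroc,
            "bar_aupr": bb["cv"].mean_aupr,
            "prm_auroc": pd_["cv"].mean_auroc,
            "prm_threshold": pd_["threshold"],
            "n_bar_bins": int(len(bb["bars"].bin_indices)),
            "n_bir_bins": int(len(bb["birs"].bin_indices)),
            "n_prm_bins": int(len(pd_["prms"].bin_indices)),
            "n_drm_bins": int(len(pd_["drms"].bin_indices)),
        }

    cl0 = ds.cell_lines[0]
    enh = stage_enhancers(ds, config, cl0, bars_by_cell[cl0], prm_scores[cl0])
    _write_regions(enh["round1"], out / "enhancers_round1.bed")
    _write_regions(enh["final"], out / "enhancers.bed")
    audit_rows = []
    for stage_name, rep in enh["reports"].items():
        for r in rep.as_rows():
            audit_rows.append({"stage": stage_name, **r})
    pd.DataFrame(audit_rows).to_csv(out / "enhancer_filters.tsv", sep="\t", index=False)

    pairs = stage_pairs(ds, config, drms_by_cell)
    pairs["selected"].to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
    summaries["pairs"] = {
        "n_tested": int(len(pairs["tested"])),
        "n_selected": int(len(pairs["selected"])),
        "ctcf_fraction": pairs["ctcf_fraction"],
    }

    mtab = stage_motifless(ds, config, hot_by_cell)
    mtab.to_csv(out / "motifless_hot.tsv", sep="\t", index=False, float_format="%.6g")
    summaries["motifless_min_z"] = float(mtab["z"].min())

    sharing = {}
    for kind, sets in region_sets_by_type.items():
        by_k, _ = reporting.sharing_by_count(sets, ds.grid)
        sharing[kind] = by_k
    (out / "sharing.json").write_text(json.dumps(sharing, indent=1, sort_keys=True))

    # per-experiment fraction of peaks within each region type (first cell
    # line), including the intergenic portions of HOT and LOT
    frac_rows = []
    types_cl0 = {k: region_sets_by_type[k][cl0] for k in region_sets_by_type}
    types_cl0["HOT_intergenic"] = motifless.intergenic_restrict(
        region_sets_by_type["HOT"][cl0], ds.annotation
    )
    types_cl0["LOT_intergenic"] = motifless.intergenic_restrict(
        region_sets_by_type["LOT"][cl0], ds.annotation
    )
    for trf in ds.trf_names:
        fr = reporting.peak_region_fractions(ds.peaksets[cl0][trf], types_cl0)
        frac_rows.append({"trf": trf, **fr})
    pd.DataFrame(frac_rows).to_csv(
        out / "peak_region_fractions.tsv", sep="\t", index=False, float_format="%.4f"
    )

    # truth-based evaluation (the planted loci are known here)
    evals = {}
    for cl in ds.cell_lines:
        pr = truth_eval(bars_by_cell[cl], ds.truth.active_loci[cl])
        evals[cl] = {"bar_base_precision": pr.base_precision, "bar_base_recall": pr.base_recall}
    summaries["truth_eval"] = evals

    manifest = {
        "config": asdict(config),
        "summaries": summaries,
    }
    (out / "summary.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=float)
    )
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=float)
    )
    return manifest
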