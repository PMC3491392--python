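"""Supervised calling of binding-active and binding-inactive regions.

Bins overlapping any TRF peak are the positive class; a chromatin-feature
classifier (by default a random forest) is trained under k-fold
cross-validation, every genome bin receives the mean score of the k fold
models, and BARs / BIRs are the bins above / below fixed score thresholds
(BIRs additionally must not overlap any peak).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .genome import BinGrid, PeakSet, RegionSet, SignalTrack, bins_overlapping

BAR_THRESHOLD = 0.9
BIR_THRESHOLD = 0.1
SCORE_DECIMALS = 3  # scores are rounded before thresholding for portability


@runtime_checkable
class BinClassifier(Protocol):
    """Contract for the pluggable per-bin classifier."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinClassifier": ...

    def score_bins(self, X: np.ndarray) -> np.ndarray: ...


class ForestBinClassifier:
    """Default classifier: bagged ensemble of randomized decision trees."""

    def __init__(self, n_estimators: int = 100, seed: int = 0, **kwargs):
        self.n_estimators = n_estimators
        self.seed = seed
        self.kwargs = kwargs
        self._model: RandomForestClassifier | None = None

    def clone(self, seed: int | None = None) -> "ForestBinClassifier":
        return ForestBinClassifier(
            self.n_estimators, self.seed if seed is None else seed, **self.kwargs
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ForestBinClassifier":
        self._model = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.seed,
            n_jobs=1,
            **self.kwargs,
        )
        self._model.fit(X, y)
        return self

    def score_bins(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier not fitted")
        proba = self._model.predict_proba(X)
        pos = list(self._model.classes_).index(1)
        return proba[:, pos]


@dataclass
class ScoreTrack:
    """Per-bin classifier score in [0, 1] for one cell line."""

    grid: BinGrid
    scores: np.ndarray
    kind: str = "BAR"  # or "PRM"
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.grid.n_bins,):
            raise ValueError("score track length != bin count")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class CVResult:
    """Per-fold accuracy and the fold-averaged genome score track."""

    fold_assignments: np.ndarray  # fold id per training example
    example_bins: np.ndarray  # global bin index per training example
    labels: np.ndarray
    auroc: list[float]
    aupr: list[float]
    score_track: ScoreTrack
    fold_negative_scores: list[np.ndarray]  # held-out negative scores per fold

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.aupr))


def feature_matrix(tracks: Sequence[SignalTrack]) -> np.ndarray:
    """Stack per-bin feature tracks into an (n_bins, n_features) matrix."""
    if not tracks:
        raise ValueError("no feature tracks")
    return np.column_stack([t.values for t in tracks])


def sample_training_bins(
    grid: BinGrid,
    peaksets: Sequence[PeakSet],
    n_pos: int = 5000,
    n_neg: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample positive (peak-overlapping) and negative bin indices.

    Positives are drawn uniformly without replacement from bins overlapping
    at least one peak of any TRF; negatives from the complement.  If fewer
    eligible bins exist than requested, all are returned with a warning.
    """
    rng = np.random.default_rng(seed)
    pos_eligible = bins_overlapping(
        [p for ps in peaksets for p in ps.peaks], grid
    )
    if len(pos_eligible) == 0:
        raise ValueError("no bins overlap any TRF peak; cannot build positives")
    mask = np.ones(grid.n_bins, dtype=bool)
    mask[pos_eligible] = False
    neg_eligible = np.flatnonzero(mask)

    def draw(eligible: np.ndarray, n: int, what: str) -> np.ndarray:
        if len(eligible) < n:
            warnings.warn(
                f"only {len(eligible)} eligible {what} bins (< {n}); using all"
            )
            return np.sort(eligible)
        return np.sort(rng.choice(eligible, size=n, replace=False))

    return draw(pos_eligible, n_pos, "positive"), draw(neg_eligible, n_neg, "negative")


def crossval_train_score(
    features: np.ndarray | Sequence[SignalTrack],
    grid: BinGrid,
    pos_bins: np.ndarray,
    neg_bins: np.ndarray,
    k: int = 10,
    classifier: ForestBinClassifier | None = None,
    seed: int = 0,
    kind: str = "BAR",
    cell_line: str = "",
    out_of_fold: bool = False,
) -> CVResult:
    """k-fold cross-validation; returns fold accuracies and genome scores.

    Each fold's model is evaluated on its held-out examples (AUROC/AUPR) and
    also scores every genome bin; the genome track is the mean of the k
    per-fold genome scores.  With ``out_of_fold=True`` a training example's
    own folds are excluded from its genome score (strict variant).
    """
    X = features if isinstance(features, np.ndarray) else feature_matrix(features)
    if X.shape[0] != grid.n_bins:
        raise ValueError("feature matrix rows != bin count")
    if k < 2:
        raise ValueError("k must be >= 2")
    bins = np.concatenate([pos_bins, neg_bins])
    y = np.concatenate([np.ones(len(pos_bins), int), np.zeros(len(neg_bins), int)])
    # k beyond the smaller class degenerates gracefully to the largest
    # stratifiable split (leave-one-out per class at the extreme)
    k = min(k, int(min(len(pos_bins), len(neg_bins))))
    base = classifier or ForestBinClassifier(seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(bins), dtype=int)
    genome_scores = np.zeros((k, grid.n_bins))
    auroc, aupr = [], []
    neg_scores: list[np.ndarray] = []
    for f, (tr, te) in enumerate(skf.split(X[bins], y)):
        folds[te] = f
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"fold {f}: training split has a single class")
        model = base.clone(seed=seed * 1000 + f)
        model.fit(X[bins[tr]], ytr)
        gs = model.score_bins(X)
        genome_scores[f] = gs
        s_te = gs[bins[te]]
        yte = y[te]
        if len(np.unique(yte)) == 2:
            auroc.append(float(roc_auc_score(yte, s_te)))
            aupr.append(float(average_precision_score(yte, s_te)))
        neg_scores.append(s_te[yte == 0])
    if out_of_fold:
        # strict variant: for each training example, average only the folds
        # in which it was held out; non-example bins keep the full mean
        mean = genome_scores.mean(axis=0)
        for f in range(k):
            te_bins = bins[folds == f]
            mean[te_bins] = genome_scores[f, te_bins]
        scores = mean
    else:
        scores = genome_scores.mean(axis=0)
    scores = np.round(np.clip(scores, 0, 1), SCORE_DECIMALS)
    track = ScoreTrack(grid, scores, kind=kind, cell_line=cell_line)
    return CVResult(
        fold_assignments=folds,
        example_bins=bins,
        labels=y,
        auroc=auroc,
        aupr=aupr,
        score_track=track,
        fold_negative_scores=neg_scores,
    )


def call_bars(
    score_track: ScoreTrack, threshold: float = BAR_THRESHOLD, cell_line: str = ""
) -> RegionSet:
    """BAR bins are those with score strictly greater than the threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    idx = np.flatnonzero(score_track.scores > threshold)
    return RegionSet.from_bins(
        score_track.grid, idx, kind="BAR",
        cell_line=cell_line or score_track.cell_line,
        scores=score_track.scores[idx],
    )


def call_birs(
    score_track: ScoreTrack,
    peaksets: Sequence[PeakSet],
    threshold: float = BIR_THRESHOLD,
    cell_line: str = "",
) -> RegionSet:
    """BIR bins: score strictly below threshold and overlapping no peak."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    low = score_track.scores < threshold
    peak_bins = bins_overlapping(
        [p for ps in peaksets for p in ps.peaks], score_track.grid
    )
    low[peak_bins] = False
    idx = np.flatnonzero(low)
    return RegionSet.from_bins(
        score_track.grid, idx, kind="BIR",
        cell_line=cell_line or score_track.cell_line,
        scores=score_track.scores[idx],
    )
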