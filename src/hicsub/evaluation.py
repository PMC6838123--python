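"""Evaluation machinery: accuracy, AUPR, cross-validation, enrichment.

Accuracy is the fraction of 100 kb bins whose predicted subcompartment
matches the reference, overall and per reference class (confusion-matrix
diagonal over row sum).  AUPR is one-vs-rest area under the
precision-recall curve with step-wise integration (no linear
interpolation, which is optimistic for PR curves).  Enrichment fold
change of a signal track in a subcompartment is the median signal over
that class divided by the median over all annotated bins.  Boundary
profiles average a signal in fixed 100 kb offsets within ±400 kb of
positions where adjacent bins switch between a given ordered label pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold

from . import classifier as clf
from . import hic_matrix as hm
from .annotate import AnnotationTrack, annotate_cell, train_models
from .autoencoder import TrainingConfig


@dataclass
class SignalTrack:
    """A grid-aligned scalar track (ChIP-seq fold change, Repli-seq, ...)."""

    bins: list[hm.GenomicBin]
    values: np.ndarray  # NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.bins) != self.values.shape[0]:
            raise ValueError("bins and values misaligned")


def read_signal_bedgraph(path: str, bins: list[hm.GenomicBin]) -> SignalTrack:
    """Average bedGraph / 4-column BED values onto a fixed bin list."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    sums: dict[tuple[str, int], float] = {}
    wts: dict[tuple[str, int], float] = {}
    index = {(b.chrom, b.start): i for i, b in enumerate(bins)}
    size = bins[0].bin_size if bins else hm.DEFAULT_BIN_SIZE
    for chrom, start, end, value in df.itertuples(index=False):
        lo = (int(start) // size) * size
        while lo < int(end):
            key = (str(chrom), lo)
            if key in index:
                overlap = min(int(end), lo + size) - max(int(start), lo)
                sums[key] = sums.get(key, 0.0) + float(value) * overlap
                wts[key] = wts.get(key, 0.0) + overlap
            lo += size
    values = np.full(len(bins), np.nan)
    for key, w in wts.items():
        values[index[key]] = sums[key] / w
    return SignalTrack(bins, values)


@dataclass
class ConfusionSummary:
    matrix: np.ndarray  # (5, 5) reference x predicted
    per_class_accuracy: dict[str, float]  # NaN for classes absent from ref
    overall_accuracy: float
    n: int


def _paired_codes(pred: AnnotationTrack, ref: AnnotationTrack) -> tuple[np.ndarray, np.ndarray]:
    if pred.bins != ref.bins:
        raise ValueError("prediction and reference tracks are on different grids")
    ok = (pred.labels != clf.NA) & (ref.labels != clf.NA)
    if not ok.any():
        raise ValueError("no bins annotated in both tracks")
    return pred.labels[ok], ref.labels[ok]


def confusion(pred: AnnotationTrack, ref: AnnotationTrack) -> ConfusionSummary:
    """5x5 confusion matrix plus per-class and overall match rates."""
    p, r = _paired_codes(pred, ref)
    m = confusion_matrix(r, p, labels=list(range(len(clf.LABELS))))
    row = m.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per = np.diag(m) / row
    per_class = {
        name: (float(per[i]) if row[i] else float("nan"))
        for i, name in enumerate(clf.LABELS)
    }
    return ConfusionSummary(m, per_class, float(np.trace(m) / m.sum()), int(m.sum()))


def accuracy(pred: AnnotationTrack, ref: AnnotationTrack) -> float:
    return confusion(pred, ref).overall_accuracy


def aupr(proba: np.ndarray, ref_codes: np.ndarray) -> dict[str, float]:
    """One-vs-rest AUPR per class (step-integrated); NaN if class absent."""
    proba = np.asarray(proba, dtype=np.float64)
    ref_codes = np.asarray(ref_codes)
    if proba.shape != (ref_codes.size, len(clf.LABELS)):
        raise ValueError("probability matrix and reference codes misaligned")
    out: dict[str, float] = {}
    for c, name in enumerate(clf.LABELS):
        truth = ref_codes == c
        out[name] = (
            float(average_precision_score(truth, proba[:, c]))
            if truth.any()
            else float("nan")
        )
    return out


def track_aupr(pred: AnnotationTrack, ref: AnnotationTrack) -> dict[str, float]:
    if pred.proba is None:
        raise ValueError("prediction track carries no probabilities")
    ok = (pred.labels != clf.NA) & (ref.labels != clf.NA)
    return aupr(pred.proba[ok], ref.labels[ok])


def kfold_cv(
    latents: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    cfg: TrainingConfig | None = None,
    seed: int = 0,
    hidden: int = clf.DEFAULT_HIDDEN,
) -> pd.DataFrame:
    """Stratified k-fold CV of the classifier on (latent, label) pairs.

    Each fold trains a fresh balanced classifier on the remaining folds
    and scores the held-out fold.  Returns one row per fold with overall
    and per-class accuracies; summary statistics are ``df.mean()`` /
    ``df.var()``.  Falls back to unstratified folds (with a warning in
    the returned attrs) when a class is smaller than k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cfg = cfg or TrainingConfig(seed=seed)
    codes = clf.encode_labels(labels)
    latents = np.asarray(latents)
    smallest = np.bincount(codes, minlength=len(clf.LABELS))
    smallest = smallest[smallest > 0].min()
    stratified = smallest >= k
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    rows = []
    for fold, (tr, te) in enumerate(splitter.split(latents, codes)):
        fold_cfg = TrainingConfig(
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, loss=cfg.loss,
            seed=cfg.seed + fold, dropout_rate=cfg.dropout_rate,
        )
        counts = np.bincount(codes[tr], minlength=len(clf.LABELS))
        if counts[np.unique(codes[tr])].min() >= 2:
            n_bal = 3 * int(counts.max()) + 1
            bset = clf.balance_training_set(latents[tr], codes[tr], n_bal, fold_cfg.seed + 2)
            params = clf.train_classifier(bset, fold_cfg, hidden)
        else:  # a class too small to interpolate: train on the raw fold
            params = clf.fit_latents(latents[tr], codes[tr], fold_cfg, hidden)
        pred = clf.predict(params, latents[te])
        row: dict[str, float] = {"fold": fold, "overall": float(np.mean(pred == codes[te]))}
        for c, name in enumerate(clf.LABELS):
            mask = codes[te] == c
            row[name] = float(np.mean(pred[mask] == c)) if mask.any() else float("nan")
        rows.append(row)
    df = pd.DataFrame(rows).set_index("fold")
    df.attrs["stratified"] = stratified
    return df


def enrichment_fold_change(signal: SignalTrack, ann: AnnotationTrack) -> dict[str, float]:
    """Median signal per subcompartment over the median across all of them.

    Operates on full-width annotated bins with a present signal value;
    truncated terminal bins are excluded so bin medians equal base-pair
    medians.  Classes with no usable bins are NaN.
    """
    if signal.bins != ann.bins:
        raise ValueError("signal and annotation tracks are on different grids")
    usable = (
        (ann.labels != clf.NA)
        & ~np.isnan(signal.values)
        & ~np.array([b.truncated for b in ann.bins])
    )
    if not usable.any():
        raise ValueError("no usable annotated bins with signal")
    global_median = float(np.median(signal.values[usable]))
    out: dict[str, float] = {}
    for c, name in enumerate(clf.LABELS):
        mask = usable & (ann.labels == c)
        out[name] = (
            float(np.median(signal.values[mask]) / global_median)
            if mask.any()
            else float("nan")
        )
    return out


def boundary_profile(
    signal: SignalTrack,
    ann: AnnotationTrack,
    pair: tuple[str, str],
    window: int = 400_000,
) -> tuple[np.ndarray, int]:
    """Mean signal in 100 kb offsets around left→right label switches.

    A boundary is the junction between two adjacent same-chromosome bins
    annotated ``pair[0]`` then ``pair[1]``.  The profile covers
    [−window, +window) in bin-size steps (8 offsets for 400 kb / 100 kb).
    Boundaries whose window runs off the chromosome, or contains an NA
    annotation or missing signal, are dropped.  Returns (profile, count);
    the profile is all-NaN when count is 0.
    """
    if signal.bins != ann.bins:
        raise ValueError("signal and annotation tracks are on different grids")
    left, right = (clf.LABEL_INDEX[pair[0]], clf.LABEL_INDEX[pair[1]])
    size = ann.bins[0].bin_size
    if window % size:
        raise ValueError("window must be a multiple of the bin size")
    half = window // size
    profiles = []
    for i in range(len(ann.bins) - 1):
        a, b = ann.bins[i], ann.bins[i + 1]
        if a.chrom != b.chrom or b.start != a.start + size:
            continue
        if ann.labels[i] != left or ann.labels[i + 1] != right:
            continue
        lo, hi = i - half + 1, i + half + 1  # offsets -half .. +half-1
        if lo < 0 or hi > len(ann.bins):
            continue
        window_bins = ann.bins[lo:hi]
        if any(w.chrom != a.chrom for w in window_bins):
            continue
        vals = signal.values[lo:hi]
        if np.any(np.isnan(vals)) or np.any(ann.labels[lo:hi] == clf.NA):
            continue
        profiles.append(vals)
    if not profiles:
        return np.full(2 * half, np.nan), 0
    return np.mean(profiles, axis=0), len(profiles)


def coverage_sweep(
    dense: hm.InterContactMatrix,
    reference: AnnotationTrack,
    rates: list[float],
    cfg: TrainingConfig | None = None,
    retrain: bool = False,
    train_keep_rate: float = 0.1,
    **train_kwargs,
) -> pd.DataFrame:
    """Coverage titration: annotation accuracy as input reads are thinned.

    Default protocol: train the model pair once at ``train_keep_rate``,
    then annotate fresh downsamplings of the dense matrix at each rate
    and score against the reference — how a single trained model behaves
    across target coverages (inputs denser than the training coverage are
    coverage-matched by :func:`annotate_cell`).  With ``retrain=True``
    the whole pipeline is instead retrained at every rate.  Both are
    deterministic under a fixed config seed.
    """
    if any(not 0 < r <= 1 for r in rates):
        raise ValueError("rates must lie in (0, 1]")
    cfg = cfg or TrainingConfig()
    models = None
    if not retrain:
        models = train_models(dense, train_keep_rate, reference, cfg, **train_kwargs)
    rows = []
    for rate in rates:
        if retrain:
            models = train_models(dense, rate, reference, cfg, **train_kwargs)
        sparse = hm.downsample(dense, rate, cfg.seed + 17)  # fresh evaluation thinning
        pred = annotate_cell(models, sparse)
        summ = confusion(pred, reference)
        row = {"keep_rate": rate, "overall": summ.overall_accuracy}
        row.update({name: summ.per_class_accuracy[name] for name in clf.LABELS})
        rows.append(row)
    return pd.DataFrame(rows)
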