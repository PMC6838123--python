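"""End-to-end pipeline: contact matrix → imputation → subcompartment track.

Training (per parity): downsample the dense matrix to the target
coverage, convert both to contact probabilities, train the denoising
autoencoder on training-chromosome rows (sparse in, dense target), encode
those rows, balance the labels, and train the MLP classifier.  The even
parity runs the identical recipe on the transposed matrices.  A bin's
label only ever comes from its own parity's model pair.

Inference on a new cell type: probability-transform its sparse matrix,
encode every covered row with the matching autoencoder, classify the
latents; bins with a zero contact marginal are reported as NA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import hic_matrix as hm
from ._nn import DenseNet
from .autoencoder import (
    DEFAULT_INTERIOR,
    AutoencoderParameters,
    TrainingConfig,
    encode,
    reconstruct,
    train_autoencoder,
)

# conventional subcompartment palette (BED9 itemRgb)
PALETTE = {
    "A1": "228,26,28",
    "A2": "255,127,0",
    "B1": "55,126,184",
    "B2": "152,78,163",
    "B3": "77,175,74",
}

# Cross-cell-type model choice: targets with at least this many
# inter-chromosomal read pairs use the 10%-coverage-trained model,
# sparser targets the 5% one.
COVERAGE_THRESHOLD = 45_000_000


@dataclass
class AnnotationTrack:
    """Per-bin subcompartment call (or NA) with 5-class probabilities."""

    bins: list[hm.GenomicBin]
    labels: np.ndarray  # integer codes, -1 = NA
    proba: np.ndarray | None = None  # (n, 5); NaN rows where NA
    cell_type: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.bins) != self.labels.shape[0]:
            raise ValueError("bins and labels misaligned")
        if self.proba is not None:
            self.proba = np.asarray(self.proba, dtype=np.float64)
            if self.proba.shape != (len(self.bins), len(clf.LABELS)):
                raise ValueError("probability matrix shape mismatch")
            ok = self.labels != clf.NA
            if ok.any() and not np.allclose(self.proba[ok].sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("probability rows of annotated bins must sum to 1")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def label_names(self) -> np.ndarray:
        names = np.array(list(clf.LABELS) + ["NA"], dtype=object)
        return names[self.labels]

    def subset(self, mask: np.ndarray) -> "AnnotationTrack":
        idx = np.flatnonzero(mask)
        return AnnotationTrack(
            [self.bins[i] for i in idx],
            self.labels[idx],
            None if self.proba is None else self.proba[idx],
            self.cell_type,
        )


def track_from_grids(
    row_grid: hm.BinGrid,
    col_grid: hm.BinGrid,
    labels: np.ndarray,
    proba: np.ndarray | None = None,
    cell_type: str = "",
) -> AnnotationTrack:
    """Track over the concatenated odd-grid + even-grid bins."""
    return AnnotationTrack(row_grid.bins + col_grid.bins, labels, proba, cell_type)


def write_bed(track: AnnotationTrack, path: str | Path, bed9: bool = False) -> int:
    """Write annotated (non-NA) bins as BED; returns record count."""
    n = 0
    with open(path, "w") as fh:
        for i, b in enumerate(track.bins):
            code = track.labels[i]
            if code == clf.NA:
                continue
            name = clf.LABELS[code]
            score = (
                int(round(1000 * track.proba[i, code])) if track.proba is not None else 0
            )
            fields = [b.chrom, str(b.start), str(b.end), name, str(score), "."]
            if bed9:
                fields += [str(b.start), str(b.end), PALETTE[name]]
            fh.write("\t".join(fields) + "\n")
            n += 1
    return n


def write_proba_tsv(track: AnnotationTrack, path: str | Path) -> None:
    rows = {
        "chrom": [b.chrom for b in track.bins],
        "start": [b.start for b in track.bins],
        "end": [b.end for b in track.bins],
        "label": track.label_names,
    }
    df = pd.DataFrame(rows)
    if track.proba is not None:
        for j, name in enumerate(clf.LABELS):
            df[f"p_{name}"] = track.proba[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, bins: list[hm.GenomicBin], cell_type: str = "") -> AnnotationTrack:
    """Load reference labels onto a bin list; unlisted bins become NA."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 3], names=["chrom", "start", "name"],
        comment="#",
    )
    lookup = {
        (str(c), int(s)): str(n) for c, s, n in zip(df["chrom"], df["start"], df["name"])
    }
    labels = np.full(len(bins), clf.NA, dtype=np.int64)
    for i, b in enumerate(bins):
        name = lookup.get((b.chrom, b.start))
        if name is not None and name in clf.LABEL_INDEX:
            labels[i] = clf.LABEL_INDEX[name]
    return AnnotationTrack(bins, labels, None, cell_type)


# ----------------------------------------------------------------------
# model bundle


@dataclass
class ModelBundle:
    """Four trained parameter sets (autoencoder + classifier per parity)."""

    odd_autoencoder: AutoencoderParameters
    odd_classifier: clf.ClassifierParameters
    even_autoencoder: AutoencoderParameters
    even_classifier: clf.ClassifierParameters
    manifest: dict = field(default_factory=dict)


def _default_train_chroms(grid: hm.BinGrid) -> list[str]:
    # first half of the parity's chromosomes — the ~51% train split
    return grid.chroms[: max(1, (len(grid.chroms) + 1) // 2)]


def _train_parity(
    sparse_p: np.ndarray,
    dense_p: np.ndarray,
    grid: hm.BinGrid,
    covered: np.ndarray,
    ref_codes: np.ndarray,
    train_chroms: list[str],
    cfg: TrainingConfig,
    interior: tuple[int, ...],
    hidden: int,
    balance_n: int | None,
    classifier_epochs: int,
) -> tuple[AutoencoderParameters, clf.ClassifierParameters, int]:
    train_mask = grid.chrom_mask(train_chroms) & covered
    if not train_mask.any():
        raise ValueError(f"no covered training rows on chromosomes {train_chroms}")
    ae, _ = train_autoencoder(sparse_p[train_mask], dense_p[train_mask], cfg, interior)
    lat = encode(ae, sparse_p[train_mask])
    codes = ref_codes[train_mask]
    labeled = codes != clf.NA
    if not labeled.any():
        raise ValueError("reference labels do not cover the training chromosomes")
    # 3x the largest class gives every class enough interpolants for the
    # small desk-scale update budget
    n = balance_n or 3 * int(np.bincount(codes[labeled], minlength=5).max()) + 1
    bset = clf.balance_training_set(lat[labeled], codes[labeled], n, cfg.seed + 2)
    clf_cfg = replace(cfg, epochs=classifier_epochs)
    mlp = clf.train_classifier(bset, clf_cfg, hidden)
    return ae, mlp, n


def train_models(
    dense: hm.InterContactMatrix,
    keep_rate: float,
    reference: AnnotationTrack,
    cfg: TrainingConfig | None = None,
    *,
    train_chroms_odd: list[str] | None = None,
    train_chroms_even: list[str] | None = None,
    interior: tuple[int, ...] = DEFAULT_INTERIOR,
    hidden: int = clf.DEFAULT_HIDDEN,
    balance_n: int | None = None,
    classifier_epochs: int = 50,
) -> ModelBundle:
    """Full training run on one dense matrix + reference annotation.

    ``reference`` must be a track over the concatenated odd + even bins
    (as produced by :func:`track_from_grids` or :func:`read_bed`).
    The classifier gets its own epoch budget (default 50): its balanced
    training sets are far smaller than the probability matrices the
    autoencoder sees, so it needs more passes to converge.
    """
    cfg = cfg or TrainingConfig()
    if len(reference) != len(dense.row_grid) + len(dense.col_grid):
        raise ValueError("reference track does not span the odd + even bin grids")
    if keep_rate >= 1.0:
        warnings.warn(
            "keep_rate is 1.0: the 'sparse' input equals the dense target, "
            "so the denoiser sees no noise (identity-noise run)",
            stacklevel=2,
        )
    sparse = hm.downsample(dense, keep_rate, cfg.seed)
    sparse_p = hm.to_probability(sparse).probs
    dense_p = hm.to_probability(dense).probs
    n_odd = len(dense.row_grid)
    odd_chroms = train_chroms_odd or _default_train_chroms(dense.row_grid)
    even_chroms = train_chroms_even or _default_train_chroms(dense.col_grid)
    odd_ae, odd_mlp, n_bal_o = _train_parity(
        sparse_p, dense_p, dense.row_grid, dense.covered_rows(),
        reference.labels[:n_odd], odd_chroms, cfg, interior, hidden, balance_n,
        classifier_epochs,
    )
    even_ae, even_mlp, n_bal_e = _train_parity(
        sparse_p.T, dense_p.T, dense.col_grid, dense.covered_cols(),
        reference.labels[n_odd:], even_chroms, cfg, interior, hidden, balance_n,
        classifier_epochs,
    )
    manifest = {
        "keep_rate": keep_rate,
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "batch_size": cfg.batch_size,
        "learning_rate": cfg.learning_rate,
        "loss": cfg.loss,
        "dropout_rate": cfg.dropout_rate,
        "hidden_width": hidden,
        "classifier_epochs": classifier_epochs,
        "interior": list(interior),
        "train_chroms_odd": odd_chroms,
        "train_chroms_even": even_chroms,
        "balance_n_odd": n_bal_o,
        "balance_n_even": n_bal_e,
        "n_odd": n_odd,
        "n_even": len(dense.col_grid),
        "training_coverage": sparse.coverage,
    }
    return ModelBundle(odd_ae, odd_mlp, even_ae, even_mlp, manifest)


def _check_grid_width(models: ModelBundle, sparse: hm.InterContactMatrix) -> None:
    want_odd = models.odd_autoencoder.layer_sizes[0]
    want_even = models.even_autoencoder.layer_sizes[0]
    if len(sparse.col_grid) != want_odd or len(sparse.row_grid) != want_even:
        raise ValueError(
            f"matrix is {len(sparse.row_grid)}x{len(sparse.col_grid)} but the models "
            f"expect {want_even}x{want_odd}; re-bin the contacts onto the training grid"
        )


def annotate_cell(
    models: ModelBundle,
    sparse: hm.InterContactMatrix,
    cell_type: str = "",
    match_coverage: bool = True,
) -> AnnotationTrack:
    """Label every covered bin of both parities; zero-marginal bins are NA.

    The denoiser was trained at one input coverage, and rows that are much
    denser than that sit off its training distribution (annotations drift
    when coverage is too high).  With ``match_coverage`` (default), inputs
    whose total count exceeds the training coverage are first thinned down
    to it — the same device used to build the training input itself.  The
    thinning seed is fixed by the model manifest, so annotation is a
    deterministic function of (models, matrix).
    """
    _check_grid_width(models, sparse)
    train_cov = models.manifest.get("training_coverage")
    if match_coverage and train_cov and sparse.coverage > train_cov:
        sparse = hm.downsample(
            sparse, train_cov / sparse.coverage, models.manifest.get("seed", 0) + 23
        )
    probs = hm.to_probability(sparse).probs
    n_odd, n_even = len(sparse.row_grid), len(sparse.col_grid)
    labels = np.full(n_odd + n_even, clf.NA, dtype=np.int64)
    proba = np.full((n_odd + n_even, len(clf.LABELS)), np.nan)
    for offset, rows, covered, ae, mlp in (
        (0, probs, sparse.covered_rows(), models.odd_autoencoder, models.odd_classifier),
        (n_odd, probs.T, sparse.covered_cols(), models.even_autoencoder, models.even_classifier),
    ):
        if covered.any():
            lat = encode(ae, rows[covered])
            p = clf.predict_proba(mlp, lat)
            idx = offset + np.flatnonzero(covered)
            proba[idx] = p
            labels[idx] = np.argmax(p, axis=1)
    return track_from_grids(sparse.row_grid, sparse.col_grid, labels, proba, cell_type)


def impute_matrix(models: ModelBundle, sparse: hm.InterContactMatrix) -> hm.ProbabilityMatrix:
    """Dense probability map from the odd model's reconstructed rows."""
    _check_grid_width(models, sparse)
    probs = hm.to_probability(sparse).probs
    dense = reconstruct(models.odd_autoencoder, probs)
    # sigmoid output is strictly inside (0, 1); clip only guards float32 rounding
    dense = np.clip(dense.astype(np.float64), 1e-12, 1.0 - 1e-12)
    return hm.ProbabilityMatrix(sparse.row_grid, sparse.col_grid, dense)


def select_parameter_set(inter_read_pairs: float, threshold: float = COVERAGE_THRESHOLD) -> str:
    """Which pre-trained bundle suits a target cell type's coverage."""
    return "keep10" if inter_read_pairs >= threshold else "keep05"


# ----------------------------------------------------------------------
# persistence: one .npz per network + a JSON manifest; exact round-trip


def _net_arrays(net: DenseNet, prefix: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {
        f"{prefix}:layer_sizes": np.array(net.layer_sizes, dtype=np.int64),
        f"{prefix}:activations": np.array(net.activations),
        f"{prefix}:dropout_layers": np.array(net.dropout_layers, dtype=bool),
        f"{prefix}:dropout_rate": np.array(net.dropout_rate),
        f"{prefix}:input_activation": np.array(net.input_activation or ""),
    }
    for i, (w, b) in enumerate(zip(net.weights, net.biases)):
        out[f"{prefix}:W{i}"] = w
        out[f"{prefix}:b{i}"] = b
    return out


def _net_from_arrays(data: dict, prefix: str) -> DenseNet:
    sizes = [int(s) for s in data[f"{prefix}:layer_sizes"]]
    inp = str(data[f"{prefix}:input_activation"])
    net = DenseNet(
        layer_sizes=sizes,
        activations=[str(a) for a in data[f"{prefix}:activations"]],
        dropout_layers=[bool(d) for d in data[f"{prefix}:dropout_layers"]],
        dropout_rate=float(data[f"{prefix}:dropout_rate"]),
        input_activation=inp or None,
    )
    net.weights = [data[f"{prefix}:W{i}"] for i in range(len(sizes) - 1)]
    net.biases = [data[f"{prefix}:b{i}"] for i in range(len(sizes) - 1)]
    return net


def save_models(models: ModelBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    arrays.update(_net_arrays(models.odd_autoencoder.net, "odd_ae"))
    arrays.update(_net_arrays(models.even_autoencoder.net, "even_ae"))
    arrays.update(_net_arrays(models.odd_classifier.net, "odd_clf"))
    arrays.update(_net_arrays(models.even_classifier.net, "even_clf"))
    arrays["latent_index"] = np.array(
        [models.odd_autoencoder.latent_index, models.even_autoencoder.latent_index]
    )
    np.savez(directory / "models.npz", **arrays)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(models.manifest, fh, indent=2, sort_keys=True)


def load_models(directory: str | Path) -> ModelBundle:
    directory = Path(directory)
    with np.load(directory / "models.npz", allow_pickle=False) as npz:
        data = {k: npz[k] for k in npz.files}
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    li = data["latent_index"]
    cfg = TrainingConfig(
        epochs=manifest.get("epochs", 25),
        batch_size=manifest.get("batch_size", 32),
        learning_rate=manifest.get("learning_rate", 0.001),
        loss=manifest.get("loss", "bce"),
        seed=manifest.get("seed", 0),
        dropout_rate=manifest.get("dropout_rate", 0.25),
    )
    return ModelBundle(
        AutoencoderParameters(_net_from_arrays(data, "odd_ae"), int(li[0]), cfg),
        clf.ClassifierParameters(_net_from_arrays(data, "odd_clf"), cfg),
        AutoencoderParameters(_net_from_arrays(data, "even_ae"), int(li[1]), cfg),
        clf.ClassifierParameters(_net_from_arrays(data, "even_clf"), cfg),
        manifest,
    )
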