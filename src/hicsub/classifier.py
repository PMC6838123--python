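"""Balanced multilayer-perceptron subcompartment classifier.

Maps 128-d latent contact embeddings to one of the five primary
subcompartments A1, A2, B1, B2, B3 (fixed index order; the tiny B4 class
is never emitted).  Architecture: a sigmoid squash of the input latent
vector, hidden ReLU layers of widths 64 and H (H = 16 by default, 32 as a
configuration switch) each followed by 25% dropout in training, and a
5-way softmax output.  Optimized with categorical cross-entropy + RMSProp.

Because subcompartments are heavily imbalanced genome-wide, the training
set is first balanced: for each class, N synthetic latent vectors are
drawn as random points on segments between pairs of same-class originals,

    r = x + (y - x) * rand(0, 1),

with N strictly greater than the largest class count, giving exactly 5·N
training samples with a uniform label marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import DenseNet
from .autoencoder import TrainingConfig

LABELS: tuple[str, ...] = ("A1", "A2", "B1", "B2", "B3")
LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(LABELS)}
NA = -1  # integer code for unannotated bins

DEFAULT_HIDDEN = 16  # alternative supported width: 32


def encode_labels(labels: np.ndarray | list) -> np.ndarray:
    """String labels → integer codes (A1=0 … B3=4); rejects anything else."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        if arr.size and (arr.min() < NA or arr.max() >= len(LABELS)):
            raise ValueError("integer labels outside the five categories")
        return arr.astype(np.int64)
    out = np.empty(arr.shape, dtype=np.int64)
    for i, v in np.ndenumerate(arr):
        if v in LABEL_INDEX:
            out[i] = LABEL_INDEX[v]
        elif v in ("NA", ".", "", None):
            out[i] = NA
        else:
            raise ValueError(f"unknown subcompartment label {v!r}")
    return out


@dataclass
class BalancedTrainingSet:
    """Exactly N interpolated samples per class, 5·N rows total."""

    vectors: np.ndarray  # (5N, d)
    labels: np.ndarray  # (5N,) integer codes
    interpolated: np.ndarray  # bool per row (all True under the literal recipe)
    parent_pairs: np.ndarray  # (5N, 2) indices into the source latents
    seed: int


def balance_training_set(
    latents: np.ndarray,
    labels: np.ndarray | list,
    n_per_class: int,
    seed: int,
) -> BalancedTrainingSet:
    """Build a class-balanced set of segment interpolants (seeded).

    Each synthetic vector lies on the segment between two randomly chosen
    same-class originals.  Requires every class to have at least two
    members and ``n_per_class`` to exceed the largest class count.
    """
    latents = np.asarray(latents, dtype=np.float64)
    codes = encode_labels(labels)
    if latents.shape[0] != codes.shape[0]:
        raise ValueError("latents and labels misaligned")
    class_members = [np.flatnonzero(codes == c) for c in range(len(LABELS))]
    counts = [len(m) for m in class_members]
    for name, n in zip(LABELS, counts):
        if n < 2:
            raise ValueError(f"class {name} has {n} member(s); need >= 2 to interpolate")
    if n_per_class <= max(counts):
        raise ValueError(
            f"n_per_class ({n_per_class}) must exceed the largest class count ({max(counts)})"
        )
    rng = np.random.default_rng(seed)
    vecs, labs, pairs = [], [], []
    for c, members in enumerate(class_members):
        xi = rng.choice(members, size=n_per_class)
        yi = rng.choice(members, size=n_per_class)
        t = rng.random((n_per_class, 1))
        x, y = latents[xi], latents[yi]
        vecs.append(x + (y - x) * t)
        labs.append(np.full(n_per_class, c, dtype=np.int64))
        pairs.append(np.column_stack([xi, yi]))
    return BalancedTrainingSet(
        vectors=np.vstack(vecs),
        labels=np.concatenate(labs),
        interpolated=np.ones(5 * n_per_class, dtype=bool),
        parent_pairs=np.vstack(pairs),
        seed=seed,
    )


@dataclass
class ClassifierParameters:
    net: DenseNet
    config: TrainingConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def layer_sizes(self) -> list[int]:
        return self.net.layer_sizes


def build_classifier(
    latent_width: int = 128,
    hidden: int = DEFAULT_HIDDEN,
    config: TrainingConfig | None = None,
) -> ClassifierParameters:
    cfg = config or TrainingConfig()
    net = DenseNet(
        layer_sizes=[latent_width, 64, hidden, len(LABELS)],
        activations=["relu", "relu", "softmax"],
        dropout_layers=[True, True, False],
        dropout_rate=cfg.dropout_rate,
        input_activation="sigmoid",
    )
    net.initialize(np.random.default_rng(cfg.seed))
    return ClassifierParameters(net=net, config=cfg)


def _one_hot(codes: np.ndarray) -> np.ndarray:
    out = np.zeros((codes.size, len(LABELS)), dtype=np.float64)
    out[np.arange(codes.size), codes] = 1.0
    return out


def fit_latents(
    vectors: np.ndarray,
    codes: np.ndarray,
    cfg: TrainingConfig,
    hidden: int = DEFAULT_HIDDEN,
) -> ClassifierParameters:
    """Train an MLP on raw (vector, label-code) pairs; used by CV too."""
    codes = np.asarray(codes)
    if codes.size and (codes.min() < 0 or codes.max() >= len(LABELS)):
        raise ValueError("labels outside the five subcompartment categories")
    params = build_classifier(np.asarray(vectors).shape[1], hidden, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    params.loss_history = params.net.fit(
        vectors,
        _one_hot(codes),
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        loss="cce",
        rng=rng,
        rho=cfg.rmsprop_decay,
        eps=cfg.rmsprop_eps,
    )
    return params


def train_classifier(
    bset: BalancedTrainingSet,
    cfg: TrainingConfig | None = None,
    hidden: int = DEFAULT_HIDDEN,
) -> ClassifierParameters:
    """Fit the subcompartment MLP on a balanced training set (seeded)."""
    return fit_latents(bset.vectors, bset.labels, cfg or TrainingConfig(), hidden)


def predict_proba(params: ClassifierParameters, latents: np.ndarray) -> np.ndarray:
    """Per-bin 5-class probabilities; rows sum to 1 (softmax output)."""
    latents = np.asarray(latents)
    if latents.ndim != 2 or latents.shape[1] != params.net.layer_sizes[0]:
        raise ValueError(
            f"latent width {latents.shape[-1] if latents.ndim else '?'} != "
            f"classifier input {params.net.layer_sizes[0]}"
        )
    return np.asarray(params.net.forward(latents), dtype=np.float64)


def predict(params: ClassifierParameters, latents: np.ndarray) -> np.ndarray:
    """Integer label codes = argmax of predict_proba; ties go to A1 first."""
    return np.argmax(predict_proba(params, latents), axis=1)
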