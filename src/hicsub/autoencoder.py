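"""Denoising autoencoder: sparse contact-probability rows → dense rows.

Each row of the inter-chromosomal probability matrix is one genomic bin's
contact profile against every bin of the opposite parity.  The network is
9 sequential affine layers of widths

    N_loci, 1024, 512, 256, 128, 256, 512, 1024, N_loci

with ReLU on hidden layers, a linearly activated 128-d latent layer (the
bin embedding used downstream), and a sigmoid output matching the [0, 1)
probability range.  Hidden layers of width 1024 and 256 — on both sides
of the bottleneck — are followed by 25% dropout during training.  The
loss is elementwise binary cross-entropy between reconstructed and dense
ground-truth probabilities (mean-squared error is available as an
alternative), optimized with mini-batch RMSProp.

For small synthetic grids the interior widths are capped at 4·N_loci so
the architecture keeps its hourglass shape at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import DenseNet, parameter_count

DEFAULT_INTERIOR = (1024, 512, 256, 128)  # encoder side; decoder mirrors it
DROPOUT_WIDTHS = (1024, 256)  # hidden widths followed by 25% dropout


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters shared by both networks in the pipeline."""

    epochs: int = 25
    batch_size: int = 32
    learning_rate: float = 0.001
    loss: str = "bce"  # "mse" supported with near-identical behaviour
    seed: int = 0
    dropout_rate: float = 0.25
    rmsprop_decay: float = 0.9  # unstated in the protocol; standard value
    rmsprop_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def autoencoder_layer_sizes(
    n_loci: int, interior: tuple[int, ...] = DEFAULT_INTERIOR
) -> list[int]:
    """Full symmetric layer list for a given input width.

    ``interior`` is the encoder half ending at the latent width; widths
    are capped at 4·n_loci so tiny fixtures keep the hourglass shape.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    capped = [max(1, min(w, 4 * n_loci)) for w in interior]
    return [n_loci, *capped, *capped[-2::-1], n_loci]


@dataclass
class AutoencoderParameters:
    """Trained weights plus the activation/dropout schedule."""

    net: DenseNet
    latent_index: int  # affine-layer index whose output is the latent code
    config: TrainingConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def layer_sizes(self) -> list[int]:
        return self.net.layer_sizes

    @property
    def latent_width(self) -> int:
        return self.net.layer_sizes[self.latent_index]

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.net.layer_sizes)


def build_autoencoder(
    n_loci: int,
    config: TrainingConfig | None = None,
    interior: tuple[int, ...] = DEFAULT_INTERIOR,
) -> AutoencoderParameters:
    """Seeded construction; parameter count equals Σ(m·n + m) over layers."""
    cfg = config or TrainingConfig()
    sizes = autoencoder_layer_sizes(n_loci, interior)
    latent_index = len(interior)
    n_affine = len(sizes) - 1
    activations = ["relu"] * n_affine
    activations[latent_index - 1] = "linear"  # the bottleneck code
    activations[-1] = "sigmoid"
    capped_dropout = {max(1, min(w, 4 * n_loci)) for w in DROPOUT_WIDTHS}
    dropout = [
        sizes[i + 1] in capped_dropout and (i + 1) not in (latent_index, n_affine)
        for i in range(n_affine)
    ]
    net = DenseNet(
        layer_sizes=sizes,
        activations=activations,
        dropout_layers=dropout,
        dropout_rate=cfg.dropout_rate,
    )
    net.initialize(np.random.default_rng(cfg.seed))
    return AutoencoderParameters(net=net, latent_index=latent_index, config=cfg)


def _check_rows(rows: np.ndarray, width: int | None = None) -> np.ndarray:
    rows = np.asarray(rows)
    if rows.ndim != 2:
        raise ValueError("expected a 2-d array of probability rows")
    if width is not None and rows.shape[1] != width:
        raise ValueError(f"row width {rows.shape[1]} != expected {width}")
    return rows


def train_autoencoder(
    sparse_rows: np.ndarray,
    dense_rows: np.ndarray,
    cfg: TrainingConfig | None = None,
    interior: tuple[int, ...] = DEFAULT_INTERIOR,
) -> tuple[AutoencoderParameters, list[float]]:
    """Fit the denoiser: inputs are sparse rows, targets dense rows.

    Both row sets must be aligned (same loci, same width) with values in
    [0, 1].  Returns the parameters and the per-epoch mean loss history;
    a fixed seed reproduces both bitwise.
    """
    sparse_rows = _check_rows(sparse_rows)
    dense_rows = _check_rows(dense_rows)
    if sparse_rows.shape != dense_rows.shape:
        raise ValueError(
            f"sparse {sparse_rows.shape} and dense {dense_rows.shape} rows misaligned"
        )
    for name, arr in (("sparse", sparse_rows), ("dense", dense_rows)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} rows must lie in [0, 1]")
    cfg = cfg or TrainingConfig()
    params = build_autoencoder(sparse_rows.shape[1], cfg, interior)
    rng = np.random.default_rng(cfg.seed + 1)  # training stream, distinct from init
    history = params.net.fit(
        sparse_rows,
        dense_rows,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        loss=cfg.loss,
        rng=rng,
        rho=cfg.rmsprop_decay,
        eps=cfg.rmsprop_eps,
    )
    params.loss_history = history
    return params, history


def encode(params: AutoencoderParameters, rows: np.ndarray) -> np.ndarray:
    """Latent codes (inference mode, no dropout; deterministic)."""
    rows = _check_rows(rows, params.net.layer_sizes[0])
    return np.asarray(params.net.forward(rows, upto=params.latent_index))


def reconstruct(params: AutoencoderParameters, rows: np.ndarray) -> np.ndarray:
    """Dense probability rows; sigmoid output so values lie in (0, 1)."""
    rows = _check_rows(rows, params.net.layer_sizes[0])
    return np.asarray(params.net.forward(rows))
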