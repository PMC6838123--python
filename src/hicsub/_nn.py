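"""Minimal feed-forward network core: dense layers, backprop, RMSProp.

Both networks in this package (the denoising autoencoder and the
subcompartment MLP) are plain stacks of affine layers with elementwise
activations, trained by mini-batch gradient descent with RMSProp updates.
Everything is float32 NumPy; all randomness flows through a single
``numpy.random.Generator`` so training is bitwise reproducible for a fixed
seed on one platform.

Supported activations: ``relu``, ``sigmoid``, ``linear``, ``softmax``
(softmax only as the final layer of a cross-entropy network).  Losses:
``bce`` (elementwise binary cross-entropy against a sigmoid output),
``cce`` (categorical cross-entropy against a softmax output), ``mse``.
Dropout is inverted dropout applied after the activation of flagged
layers, training mode only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32
_EPS = 1e-7  # clamp for logs inside the cross-entropy losses


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable two-sided form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=1, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=1, keepdims=True)


_FORWARD = {
    "relu": relu,
    "sigmoid": sigmoid,
    "linear": lambda z: z,
    "softmax": softmax,
}


def bce_loss(yhat: np.ndarray, y: np.ndarray) -> float:
    """Mean per-element binary cross-entropy."""
    p = np.clip(yhat, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cce_loss(yhat: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean per-sample categorical cross-entropy."""
    p = np.clip(yhat, _EPS, 1.0)
    return float(-np.mean(np.sum(y_onehot * np.log(p), axis=1)))


def mse_loss(yhat: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((yhat - y) ** 2))


_LOSSES = {"bce": bce_loss, "cce": cce_loss, "mse": mse_loss}


@dataclass
class DenseNet:
    """A stack of affine layers ``z_i = g_i(W_i x_i + b_i)``.

    Parameters
    ----------
    layer_sizes
        Widths including input and output, e.g. ``[400, 64, 16, 5]``.
    activations
        One activation name per affine layer (``len(layer_sizes) - 1``).
    dropout_layers
        Booleans, one per affine layer: apply dropout after that layer's
        activation while training.  Never applied at inference.
    dropout_rate
        Fraction of units zeroed on flagged layers (inverted dropout).
    input_activation
        Optional fixed elementwise squash applied to the raw input before
        the first affine layer (the subcompartment classifier passes its
        latent vectors through a sigmoid here).  It has no parameters.
    """

    layer_sizes: list[int]
    activations: list[str]
    dropout_layers: list[bool]
    dropout_rate: float = 0.25
    input_activation: str | None = None
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_layers = len(self.layer_sizes) - 1
        if n_layers < 1:
            raise ValueError("need at least one affine layer")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError(f"non-positive layer size in {self.layer_sizes}")
        if len(self.activations) != n_layers or len(self.dropout_layers) != n_layers:
            raise ValueError("activations/dropout_layers must match layer count")
        for g in self.activations:
            if g not in _FORWARD:
                raise ValueError(f"unknown activation {g!r}")

    # ------------------------------------------------------------------
    def initialize(self, rng: np.random.Generator) -> None:
        """Seeded He-uniform fan-in initialization: W ~ U(-s, s), s = sqrt(6/n_in).

        The sqrt(6) gain keeps activation variance stable through ReLU
        stacks, which matters for the small update budgets used here.
        """
        self.weights, self.biases = [], []
        for n_in, n_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            s = np.sqrt(6.0) / np.sqrt(n_in)
            self.weights.append(rng.uniform(-s, s, size=(n_out, n_in)).astype(DTYPE))
            self.biases.append(np.zeros(n_out, dtype=DTYPE))

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.layer_sizes)

    # ------------------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        *,
        training: bool = False,
        rng: np.random.Generator | None = None,
        upto: int | None = None,
    ) -> np.ndarray | tuple[list[np.ndarray], list[np.ndarray]]:
        """Run the network on a (n_samples, n_in) batch.

        At inference (default) returns the activation of layer ``upto``
        (default: the output layer).  With ``training=True`` returns the
        full ``(pre_activations, activations)`` caches for backprop;
        ``activations[0]`` is the (possibly squashed) input.
        """
        a = np.asarray(x, dtype=DTYPE)
        if a.ndim != 2 or a.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input width {a.shape[-1] if a.ndim else '?'} != "
                f"expected {self.layer_sizes[0]}"
            )
        if self.input_activation is not None:
            a = _FORWARD[self.input_activation](a)
        n_layers = len(self.weights)
        stop = n_layers if upto is None else upto
        zs: list[np.ndarray] = []
        acts: list[np.ndarray] = [a]
        masks: list[np.ndarray | None] = []
        for i in range(stop):
            z = a @ self.weights[i].T + self.biases[i]
            a = _FORWARD[self.activations[i]](z)
            mask = None
            if training and self.dropout_layers[i] and self.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(a.shape) < keep).astype(DTYPE) / DTYPE(keep)
                a = a * mask
            zs.append(z)
            acts.append(a)
            masks.append(mask)
        if training:
            self._dropout_masks = masks
            return zs, acts
        return a

    # ------------------------------------------------------------------
    def _backward(
        self,
        zs: list[np.ndarray],
        acts: list[np.ndarray],
        y: np.ndarray,
        loss: str,
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of the mean loss w.r.t. weights and biases."""
        n = y.shape[0]
        yhat = acts[-1]
        out_act = self.activations[-1]
        # fused output-layer deltas for the canonical pairings
        if loss == "bce" and out_act == "sigmoid":
            delta = (yhat - y) / DTYPE(y.size)
        elif loss == "cce" and out_act == "softmax":
            delta = (yhat - y) / DTYPE(n)
        elif loss == "mse":
            dy = 2.0 * (yhat - y) / DTYPE(y.size)
            delta = dy * _act_grad(out_act, zs[-1], yhat)
        else:
            raise ValueError(f"unsupported loss/output pairing {loss}/{out_act}")
        gw: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        gb: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        masks = getattr(self, "_dropout_masks", [None] * len(self.weights))
        for i in range(len(self.weights) - 1, -1, -1):
            gw[i] = delta.T @ acts[i]
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i]
                if masks[i - 1] is not None:  # dropped units pass no gradient
                    delta = delta * masks[i - 1]
                # activation gradient uses the pre-dropout activation
                pre_drop = acts[i] if masks[i - 1] is None else _FORWARD[
                    self.activations[i - 1]
                ](zs[i - 1])
                delta = delta * _act_grad(self.activations[i - 1], zs[i - 1], pre_drop)
        return gw, gb

    # ------------------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        loss: str,
        rng: np.random.Generator,
        rho: float = 0.9,
        eps: float = 1e-7,
    ) -> list[float]:
        """Mini-batch RMSProp training; returns the mean loss per epoch."""
        if loss not in _LOSSES:
            raise ValueError(f"unknown loss {loss!r}")
        if not self.weights:
            self.initialize(rng)
        x = np.asarray(x, dtype=DTYPE)
        y = np.asarray(y, dtype=DTYPE)
        if x.shape[0] != y.shape[0]:
            raise ValueError("input/target row counts differ")
        n = x.shape[0]
        cache_w = [np.zeros_like(w) for w in self.weights]
        cache_b = [np.zeros_like(b) for b in self.biases]
        history: list[float] = []
        loss_fn = _LOSSES[loss]
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                zs, acts = self.forward(x[idx], training=True, rng=rng)
                epoch_loss += loss_fn(acts[-1], y[idx]) * len(idx)
                gw, gb = self._backward(zs, acts, y[idx], loss)
                for i in range(len(self.weights)):
                    cache_w[i] = rho * cache_w[i] + (1.0 - rho) * gw[i] ** 2
                    cache_b[i] = rho * cache_b[i] + (1.0 - rho) * gb[i] ** 2
                    self.weights[i] -= (
                        learning_rate * gw[i] / (np.sqrt(cache_w[i]) + eps)
                    ).astype(DTYPE)
                    self.biases[i] -= (
                        learning_rate * gb[i] / (np.sqrt(cache_b[i]) + eps)
                    ).astype(DTYPE)
            history.append(epoch_loss / n)
        return history


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(DTYPE)
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "linear":
        return np.ones_like(z)
    raise ValueError(f"no elementwise gradient for {name!r}")


def parameter_count(layer_sizes: list[int]) -> int:
    """Closed-form Σ (n_in·n_out + n_out) without allocating any arrays."""
    return sum(m * n + m for n, m in zip(layer_sizes[:-1], layer_sizes[1:]))
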