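"""Autoencoder dimensionality reduction for gene feature vectors.

An encoder maps the n-dimensional input x down to an m-dimensional code y
(m < n); a decoder mirroring the encoder widths maps y back to a
reconstruction z.  Both are trained jointly by mini-batch gradient descent
on the mean squared reconstruction error ||x - z||^2.  The code-layer
output is the reduced representation handed to the classifier.

Plain SGD with a fixed learning rate keeps runs exactly reproducible for a
fixed seed.  With identity activations the optimum coincides with the
principal-component subspace of the data, which provides an external check
on the training code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import TrainingError, ValidationError

logger = logging.getLogger(__name__)

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f' as a function of the activation output)
    "identity": (lambda a: a, lambda out: np.ones_like(out)),
    "sigmoid": (lambda a: 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60))), lambda out: out * (1.0 - out)),
    "relu": (lambda a: np.maximum(a, 0.0), lambda out: (out > 0).astype(float)),
    "tanh": (np.tanh, lambda out: 1.0 - out ** 2),
}


@dataclass(frozen=True)
class AEParams:
    """Autoencoder hyperparameters.

    ``layer_sizes`` lists the encoder widths from the input dimension n down
    to the code dimension m; the decoder mirrors them in reverse.  The
    hidden/code layers use ``activation``; the output layer is identity so
    reconstructions live on the input scale.
    """

    layer_sizes: tuple[int, ...] = (512, 200)
    activation: str = "sigmoid"
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2:
            raise ValidationError("layer_sizes needs at least input and code widths")
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError(f"layer_sizes must be strictly decreasing (code m < input n), got {sizes}")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}; choose from {sorted(_ACTIVATIONS)}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be > 0")


@dataclass
class Encoder:
    """Trained encoder/decoder weight stacks plus the training loss trace."""

    weights: list[np.ndarray]          # encoder W per layer, shape (in, out)
    biases: list[np.ndarray]
    dec_weights: list[np.ndarray]      # decoder, mirrored widths
    dec_biases: list[np.ndarray]
    activation: str
    loss_trace: list[float] = field(default_factory=list)
    mean_: np.ndarray | None = None    # set when standardize was on
    scale_: np.ndarray | None = None

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def code_dim(self) -> int:
        return self.weights[-1].shape[1]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValidationError(
                f"expected matrix with {self.input_dim} columns, got shape {X.shape}")
        if self.mean_ is not None:
            X = (X - self.mean_) / self.scale_
        return X

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = self._prepare(X)
        act = _ACTIVATIONS[self.activation][0]
        h = X
        for W, b in zip(self.weights, self.biases):
            h = act(h @ W + b)
        return h

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Forward pass through encoder and decoder (output layer identity),
        on the (possibly standardized) internal scale."""
        h = self.encode(X)
        act = _ACTIVATIONS[self.activation][0]
        last = len(self.dec_weights) - 1
        for i, (W, b) in enumerate(zip(self.dec_weights, self.dec_biases)):
            h = h @ W + b
            if i != last:
                h = act(h)
        return h


def train_autoencoder(X: np.ndarray, params: AEParams) -> Encoder:
    """Train the mirrored autoencoder on X (rows = genes) and return the
    Encoder with its per-epoch loss trace.  Deterministic for a fixed seed."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"X must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite entries")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 rows to train")
    sizes = params.layer_sizes
    if X.shape[1] != sizes[0]:
        raise ValidationError(f"X has {X.shape[1]} columns but layer_sizes[0] = {sizes[0]}")

    mean_ = scale_ = None
    if params.standardize:
        mean_ = X.mean(axis=0)
        scale_ = X.std(axis=0)
        scale_[scale_ == 0] = 1.0
        X = (X - mean_) / scale_
        logger.info("standardized %d input columns", X.shape[1])

    rng = np.random.default_rng(params.seed)
    widths = list(sizes) + list(sizes[-2::-1])  # encoder then mirrored decoder

    def glorot(n_in: int, n_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    Ws = [glorot(a, b) for a, b in zip(widths, widths[1:])]
    bs = [np.zeros(b) for b in widths[1:]]
    n_enc = len(sizes) - 1
    act, dact = _ACTIVATIONS[params.activation]
    n = X.shape[0]
    n_layers = len(Ws)
    loss_trace: list[float] = []

    def full_forward(batch: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        outs = [batch]
        h = batch
        for i in range(n_layers):
            h = h @ Ws[i] + bs[i]
            if i != n_layers - 1:
                h = act(h)
            outs.append(h)
        return outs, h

    for epoch in range(params.epochs):
        order = rng.permutation(n)
        for start in range(0, n, params.batch_size):
            idx = order[start:start + params.batch_size]
            batch = X[idx]
            outs, z = full_forward(batch)
            # d(mean_rows ||x-z||^2)/dz
            delta = 2.0 * (z - batch) / batch.shape[0]
            for i in range(n_layers - 1, -1, -1):
                if i != n_layers - 1:
                    delta = delta * dact(outs[i + 1])
                gW = outs[i].T @ delta
                gb = delta.sum(axis=0)
                delta = delta @ Ws[i].T
                Ws[i] -= params.learning_rate * gW
                bs[i] -= params.learning_rate * gb
        _, z = full_forward(X)
        epoch_loss = float(np.mean(np.sum((X - z) ** 2, axis=1)))
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"loss diverged at epoch {epoch + 1}")
        loss_trace.append(epoch_loss)

    logger.info("autoencoder %s: loss %.5g -> %.5g over %d epochs",
                "->".join(map(str, sizes)), loss_trace[0], loss_trace[-1], params.epochs)
    return Encoder(
        weights=Ws[:n_enc], biases=bs[:n_enc],
        dec_weights=Ws[n_enc:], dec_biases=bs[n_enc:],
        activation=params.activation, loss_trace=loss_trace,
        mean_=mean_, scale_=scale_,
    )


def encode(encoder: Encoder, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass to the code layer; row order preserved."""
    return encoder.encode(X)


def reconstruction_error(encoder: Encoder, X: np.ndarray) -> float:
    """Mean over rows of the squared Euclidean distance between x and its
    reconstruction z (computed on the standardized scale when that was used
    in training)."""
    Xp = encoder._prepare(X)
    Z = encoder.reconstruct(X)
    return float(np.mean(np.sum((Xp - Z) ** 2, axis=1)))
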