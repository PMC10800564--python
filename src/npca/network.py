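"""The nPCA network: a multilayer perceptron whose first hidden layer is a
2-unit linear projection (no bias, no activation) and whose remaining layers
form a nonlinear decoder trained to reconstruct the input.

Architecture (m = number of features, d = decoder width, default 32)::

    input (m) --W_enc (m×2, linear)--> bottleneck (2)
        --W1 (2×d) + b1, act--> hidden (d)
        --W2 (d×d) + b2, act--> hidden (d)
        --W3 (d×m) + b3, identity--> output (m)

The bottleneck activations are the two components of the reduced
representation; after training the decoder is discarded and the m×2 encoder
matrix is the linear projection.  The encoder is initialized at the top-2 PCA
loadings of the (standardized) data, so training starts exactly at the PCA
solution and stochastic gradient descent then tilts the projection toward
directions a nonlinear decoder can reconstruct better.

Loss convention: ``E = ½ · mean((y − x)²)`` over all n·m entries, computed on
per-feature standardized data.  Under this convention the zero predictor gives
E = 0.5, and ``variance captured = (1 − 2E)·100`` is a percentage of the total
variance, reducing to 100·(λ₁+λ₂)/Σλ in the purely linear limit.

Everything here is plain float64 NumPy; determinism comes from seeding
``numpy.random.default_rng`` for both weight initialization and mini-batch
shuffling, so identical (data, config) pairs give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .data import DataMatrix, svd_pca

__all__ = [
    "NPCAParams",
    "TrainConfig",
    "TrainResult",
    "ACTIVATIONS",
    "init_model",
    "forward",
    "encode",
    "reconstruction_loss",
    "variance_captured",
    "gradients",
    "train",
]

# activation name -> (f, f') evaluated on the pre-activation
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
    "relu": (
        lambda z: np.maximum(z, 0.0),
        lambda z: (z > 0.0).astype(np.float64),
    ),
}

N_COMPONENTS = 2  # the bottleneck width is fixed: this is a 2-component method


@dataclass
class NPCAParams:
    """Weights of the nPCA network.

    ``encoder_weights`` (m×2) is the bias-free, activation-free linear
    projection.  ``decoder_weights`` are the three decoder matrices with
    shapes 2×d, d×d, d×m and ``decoder_biases`` the matching bias vectors
    (d, d, m).  The output layer has identity activation.
    """

    encoder_weights: np.ndarray
    decoder_weights: list[np.ndarray]
    decoder_biases: list[np.ndarray]
    hidden_width: int = 32
    activation_name: str = "tanh"

    def __post_init__(self) -> None:
        m, k = self.encoder_weights.shape
        d = self.hidden_width
        expected = [(k, d), (d, d), (d, m)]
        got = [w.shape for w in self.decoder_weights]
        if got != expected:
            raise ValueError(f"decoder weight shapes {got} != expected {expected}")
        if [b.shape for b in self.decoder_biases] != [(d,), (d,), (m,)]:
            raise ValueError("decoder bias shapes inconsistent with hidden width")
        if self.activation_name not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation_name!r}; "
                f"choose from {sorted(ACTIVATIONS)}"
            )

    @property
    def n_features(self) -> int:
        return self.encoder_weights.shape[0]

    def copy(self) -> "NPCAParams":
        return NPCAParams(
            encoder_weights=self.encoder_weights.copy(),
            decoder_weights=[w.copy() for w in self.decoder_weights],
            decoder_biases=[b.copy() for b in self.decoder_biases],
            hidden_width=self.hidden_width,
            activation_name=self.activation_name,
        )


@dataclass
class TrainConfig:
    """SGD hyperparameters.

    ``batch_size`` may be an integer or ``"full"``; it is clamped to n at use
    time.  ``freeze_encoder=True`` keeps the first-layer weights fixed at their
    PCA initialization throughout training (the PCA benchmark network).
    ``snapshot_every=0`` disables embedding snapshots.  Early stopping: stop
    when the full-data loss has not improved by more than ``min_delta`` for
    ``patience`` consecutive epochs (``patience=0`` disables it).
    """

    learning_rate: float = 0.01
    epochs: int = 2000
    batch_size: Union[int, str] = 32
    seed: int = 0
    freeze_encoder: bool = False
    snapshot_every: int = 0
    patience: int = 50
    min_delta: float = 1e-7

    def __post_init__(self) -> None:
        if not (self.learning_rate > 0 and np.isfinite(self.learning_rate)):
            raise ValueError("learning_rate must be positive and finite")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != "full" and int(self.batch_size) < 1:
            raise ValueError("batch_size must be >= 1 or 'full'")
        if self.snapshot_every < 0 or self.patience < 0 or self.min_delta < 0:
            raise ValueError("snapshot_every, patience, min_delta must be >= 0")


@dataclass
class TrainResult:
    """Outcome of a training run.

    ``loss_history[t]`` is the full-data loss E after epoch t+1;
    ``final_loss`` is its last entry.  ``embedding_snapshots`` is a list of
    (epoch, n×2 embedding) pairs (epoch 0 = initialization) when snapshots
    were requested.  ``variance_captured_pct`` = (1 − 2·final_loss)·100.
    """

    model: NPCAParams
    final_loss: float
    loss_history: np.ndarray
    embedding_snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)
    variance_captured_pct: float = 0.0
    stopped_epoch: int = 0


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=np.float64)


def init_model(
    X: DataMatrix,
    hidden_width: int = 32,
    activation_name: str = "tanh",
    seed: int = 0,
) -> NPCAParams:
    """Build an nPCA model for (standardized) data ``X``.

    The encoder is set to the top-2 PCA loadings of X; decoder weights are
    drawn from a seeded uniform(±√(6/(fan_in+fan_out))) scheme and biases
    start at zero.  The same seed always gives a bit-identical model.
    """
    if hidden_width < 1:
        raise ValueError("hidden_width must be >= 1")
    basis = svd_pca(X, N_COMPONENTS)
    rng = np.random.default_rng(seed)
    d, m = hidden_width, X.n_features
    shapes = [(N_COMPONENTS, d), (d, d), (d, m)]
    weights = []
    for fan_in, fan_out in shapes:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    biases = [np.zeros(d), np.zeros(d), np.zeros(m)]
    return NPCAParams(
        encoder_weights=basis.loadings,
        decoder_weights=weights,
        decoder_biases=biases,
        hidden_width=d,
        activation_name=activation_name,
    )


def encode(model: NPCAParams, X) -> np.ndarray:
    """The reduced representation: exactly ``X · encoder_weights``."""
    values = _as_values(X)
    if values.shape[1] != model.n_features:
        raise ValueError(
            f"data has {values.shape[1]} features, model expects {model.n_features}"
        )
    return values @ model.encoder_weights


def _forward_pass(model: NPCAParams, values: np.ndarray):
    """Full forward pass returning every intermediate needed for backprop."""
    act, _ = ACTIVATIONS[model.activation_name]
    w1, w2, w3 = model.decoder_weights
    b1, b2, b3 = model.decoder_biases
    z0 = values @ model.encoder_weights          # bottleneck, linear
    z1 = z0 @ w1 + b1
    h1 = act(z1)
    z2 = h1 @ w2 + b2
    h2 = act(z2)
    y = h2 @ w3 + b3                             # identity output
    return z0, z1, h1, z2, h2, y


def forward(model: NPCAParams, X) -> tuple[np.ndarray, np.ndarray]:
    """Return (embedding n×2, reconstruction n×m)."""
    values = _as_values(X)
    if values.shape[1] != model.n_features:
        raise ValueError(
            f"data has {values.shape[1]} features, model expects {model.n_features}"
        )
    z0, _, _, _, _, y = _forward_pass(model, values)
    return z0, y


def reconstruction_loss(reconstruction: np.ndarray, X) -> float:
    """E = ½ · mean over all n·m entries of (y − x)²."""
    values = _as_values(X)
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    if reconstruction.shape != values.shape:
        raise ValueError(
            f"shape mismatch: reconstruction {reconstruction.shape} vs data {values.shape}"
        )
    # divergence is reported via the non-finite check downstream, not a warning
    with np.errstate(over="ignore"):
        return 0.5 * float(np.mean((reconstruction - values) ** 2))


def variance_captured(E: float) -> float:
    """Percentage of variance captured: (1 − 2E)·100.

    May be negative for a predictor worse than the zero map; no clamping.
    """
    return (1.0 - 2.0 * E) * 100.0


def gradients(model: NPCAParams, X_batch) -> dict:
    """Analytic gradients of E on the batch w.r.t. every weight and bias.

    Returns a dict with keys ``encoder_weights``, ``decoder_weights`` (list of
    3) and ``decoder_biases`` (list of 3), each shaped like the parameter.
    Encoder gradients are always computed; a frozen-encoder training run
    simply does not apply them.
    """
    values = _as_values(X_batch)
    if values.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    n, m = values.shape
    _, dact = ACTIVATIONS[model.activation_name]
    w1, w2, w3 = model.decoder_weights
    z0, z1, h1, z2, h2, y = _forward_pass(model, values)
    for name, arr in (("bottleneck", z0), ("hidden-1", h1), ("hidden-2", h2), ("output", y)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite activations in the {name} layer; "
                "reduce the learning rate"
            )
    # dE/dY under the per-entry-mean convention
    delta3 = (y - values) / (n * m)
    g_w3 = h2.T @ delta3
    g_b3 = delta3.sum(axis=0)
    delta2 = (delta3 @ w3.T) * dact(z2)
    g_w2 = h1.T @ delta2
    g_b2 = delta2.sum(axis=0)
    delta1 = (delta2 @ w2.T) * dact(z1)
    g_w1 = z0.T @ delta1
    g_b1 = delta1.sum(axis=0)
    delta0 = delta1 @ w1.T
    g_enc = values.T @ delta0
    return {
        "encoder_weights": g_enc,
        "decoder_weights": [g_w1, g_w2, g_w3],
        "decoder_biases": [g_b1, g_b2, g_b3],
    }


def train(
    X: DataMatrix,
    config: Optional[TrainConfig] = None,
    model: Optional[NPCAParams] = None,
) -> TrainResult:
    """Train by mini-batch SGD; ``X`` is expected to be standardized.

    If no model is given one is initialized from ``config.seed``.  The loss
    history records the full-data E after every epoch.  With
    ``freeze_encoder`` the encoder weights are bit-identical before and after
    training.  Raises if the loss becomes non-finite (divergence).
    """
    config = config or TrainConfig()
    if model is None:
        model = init_model(X, seed=config.seed)
    else:
        model = model.copy()
    values = X.values
    n = values.shape[0]
    batch = n if config.batch_size == "full" else min(int(config.batch_size), n)
    rng = np.random.default_rng(config.seed)
    lr = config.learning_rate
    frozen = config.freeze_encoder
    encoder_before = model.encoder_weights.copy()

    snapshots: list[tuple[int, np.ndarray]] = []
    if config.snapshot_every > 0:
        snapshots.append((0, encode(model, values)))

    history: list[float] = []
    best = np.inf
    stale = 0
    stopped = config.epochs
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            g = gradients(model, values[idx])
            if not frozen:
                model.encoder_weights -= lr * g["encoder_weights"]
            for w, gw in zip(model.decoder_weights, g["decoder_weights"]):
                w -= lr * gw
            for b, gb in zip(model.decoder_biases, g["decoder_biases"]):
                b -= lr * gb
        _, recon = forward(model, values)
        loss = reconstruction_loss(recon, values)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (E is non-finite); "
                "try a smaller learning rate"
            )
        history.append(loss)
        if config.snapshot_every > 0 and epoch % config.snapshot_every == 0:
            snapshots.append((epoch, encode(model, values)))
        if loss < best - config.min_delta:
            best = loss
            stale = 0
        else:
            stale += 1
            if config.patience > 0 and stale >= config.patience:
                stopped = epoch
                break

    if frozen and not np.array_equal(model.encoder_weights, encoder_before):
        raise AssertionError("frozen encoder was modified during training")

    final = history[-1]
    return TrainResult(
        model=model,
        final_loss=final,
        loss_history=np.asarray(history),
        embedding_snapshots=snapshots,
        variance_captured_pct=variance_captured(final),
        stopped_epoch=min(stopped, len(history)),
    )
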