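"""Stacked autoencoders with greedy layerwise pretraining.

A five-layer autoencoder (input, three hidden layers, output of the input
size) compresses data through a low-dimensional bottleneck: its first two
weight layers are the encoder, its last two the decoder.  Deep sigmoid
autoencoders are hard to train from a cold start, so initialization proceeds
greedily: a three-layer autoencoder is trained on the data, its hidden codes
become the training set for a second three-layer autoencoder, and the weights
of both are copied into the five-layer stack before optional end-to-end
fine-tuning.

Reconstruction quality is scored by the sum of absolute deviations between
data and reconstruction over every matrix entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_net import NetParams, TrainConfig, forward, init_params, train_net

__all__ = [
    "AEArchitecture",
    "AEModel",
    "SPECTRUM_ARCH",
    "SENSORY_ARCH",
    "train_ae3",
    "pretrain_ae5",
    "finetune_ae5",
    "encode",
    "decode",
    "reconstruction_error",
]


@dataclass(frozen=True)
class AEArchitecture:
    """Shape of a five-layer autoencoder: M -> K -> D -> K -> M.

    ``input_dim`` (M) is the data dimension, ``outer_hidden`` (K) the width of
    the first and third hidden layers, ``code_dim`` (D) the bottleneck.
    """

    input_dim: int
    outer_hidden: int
    code_dim: int
    role: str = ""

    def __post_init__(self) -> None:
        if min(self.input_dim, self.outer_hidden, self.code_dim) < 1:
            raise ValueError("all dimensions must be positive")
        if not self.code_dim < self.outer_hidden < self.input_dim:
            warnings.warn(
                f"no bottleneck structure: expected D < K < M, got "
                f"D={self.code_dim}, K={self.outer_hidden}, M={self.input_dim}",
                stacklevel=2,
            )

    @property
    def layer_sizes(self) -> list[int]:
        return [
            self.input_dim,
            self.outer_hidden,
            self.code_dim,
            self.outer_hidden,
            self.input_dim,
        ]


#: Default shapes: 212 spectrum bins compress 212->85->45, 144 sensory
#: descriptors compress 144->65->30.
SPECTRUM_ARCH = AEArchitecture(212, 85, 45, role="spectrum")
SENSORY_ARCH = AEArchitecture(144, 65, 30, role="sensory")


@dataclass
class AEModel:
    """A five-layer autoencoder: parameters, architecture and training log."""

    params: NetParams
    architecture: AEArchitecture
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.params.layer_sizes != self.architecture.layer_sizes:
            raise ValueError(
                f"parameter shapes {self.params.layer_sizes} do not match "
                f"architecture {self.architecture.layer_sizes}"
            )

    @property
    def code_dim(self) -> int:
        return self.architecture.code_dim


def _check_data(data: np.ndarray, dim: int | None = None) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError(f"data must be a nonempty 2-D matrix, got shape {data.shape}")
    if dim is not None and data.shape[1] != dim:
        raise ValueError(f"data has {data.shape[1]} columns, expected {dim}")
    return data


def train_ae3(
    data: np.ndarray,
    hidden_dim: int,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    epochs: int | None = None,
) -> tuple[NetParams, list[float]]:
    """Train a three-layer (single hidden) autoencoder on (x, x) pairs.

    Returns the trained [M, H, M] parameters and the per-epoch loss log.
    """
    data = _check_data(data)
    if hidden_dim < 1:
        raise ValueError("hidden_dim must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    params = init_params([data.shape[1], hidden_dim, data.shape[1]], config.init_range, rng)
    log = train_net(params, data, data, config, rng, epochs=epochs)
    return params, log


def pretrain_ae5(
    data: np.ndarray,
    arch: AEArchitecture,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    epochs: int | None = None,
) -> AEModel:
    """Greedy pretraining: two three-layer autoencoders copied into one stack.

    Stage 1 trains an [M, K, M] autoencoder on the data; stage 2 trains a
    [K, D, K] autoencoder on the stage-1 hidden codes (sigmoid outputs in
    (0, 1), used as-is); the five-layer [M, K, D, K, M] model takes its outer
    weight layers from stage 1 and its inner pair from stage 2.  At copy time
    the stack's encoder output is bit-identical to the stage-1 encoder.
    """
    data = _check_data(data, arch.input_dim)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    outer, _ = train_ae3(data, arch.outer_hidden, config, rng, epochs=epochs)
    codes = forward(outer, data)[1]
    inner, _ = train_ae3(codes, arch.code_dim, config, rng, epochs=epochs)
    params = NetParams(
        weights=[
            outer.weights[0].copy(),
            inner.weights[0].copy(),
            inner.weights[1].copy(),
            outer.weights[1].copy(),
        ],
        biases=[
            outer.biases[0].copy(),
            inner.biases[0].copy(),
            inner.biases[1].copy(),
            outer.biases[1].copy(),
        ],
    )
    return AEModel(params=params, architecture=arch)


def finetune_ae5(
    model: AEModel,
    data: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    epochs: int | None = None,
) -> AEModel:
    """End-to-end training of the assembled five-layer autoencoder.

    Mutates the model parameters in place and extends its training log.
    Zero epochs is a no-op.
    """
    data = _check_data(data, model.architecture.input_dim)
    n_epochs = config.epochs if epochs is None else epochs
    if n_epochs == 0:
        return model
    rng = np.random.default_rng(config.seed) if rng is None else rng
    log = train_net(model.params, data, data, config, rng, epochs=n_epochs)
    model.training_log.extend(log)
    return model


def encode(model: AEModel, x: np.ndarray) -> np.ndarray:
    """Bottleneck codes: the first two affine+sigmoid stages applied to x."""
    return forward(model.params, np.asarray(x, dtype=float))[2]


def decode(model: AEModel, code: np.ndarray) -> np.ndarray:
    """Reconstruction from codes: the last two affine+sigmoid stages."""
    code = np.asarray(code, dtype=float)
    half = NetParams(model.params.weights[2:], model.params.biases[2:])
    return forward(half, code)[-1]


def reconstruct(model: AEModel, data: np.ndarray) -> np.ndarray:
    """Full forward pass (equals decode(encode(x)) elementwise)."""
    return forward(model.params, np.asarray(data, dtype=float))[-1]


def reconstruction_error(model: AEModel, data: np.ndarray) -> float:
    """Sum of absolute deviations |x - y| over every entry of the dataset."""
    data = _check_data(data, model.architecture.input_dim)
    return float(np.abs(data - reconstruct(model, data)).sum())
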