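"""Sigmoid feed-forward networks trained by per-sample stochastic gradient descent.

This module is the numerical core shared by the autoencoders, the latent-space
mapper and the assembled nine-layer spectrum-to-sensory model.  A network is a
plain stack of affine maps followed by elementwise logistic activations (the
input layer applies no activation).  Training uses the update rule

    w(t+1) = w(t) - eta * dE/dw + alpha * (w(t) - w(t-1)) + noise

applied per sample, where ``eta = eta0 * decay**t`` decays with the epoch
index ``t``, ``alpha`` is a momentum coefficient, and ``noise`` is an optional
zero-mean Gaussian perturbation with standard deviation
``noise_coeff * sqrt(2 * eta)`` intended to shake the weights out of poor
local minima.  The per-sample loss is a squared-error sum plus an L1 (lasso)
penalty on every weight and bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "NetParams",
    "TrainConfig",
    "GradState",
    "sigmoid",
    "forward",
    "sample_loss",
    "l1_penalty",
    "backprop",
    "sgd_step",
    "lr_schedule",
    "init_params",
    "glorot_init",
    "train_net",
    "save_params",
    "load_params",
]


def sigmoid(a: np.ndarray) -> np.ndarray:
    """Elementwise logistic function 1 / (1 + exp(-a)).

    Saturates smoothly for large |a|; never overflows to NaN.
    """
    return expit(np.asarray(a, dtype=float))


@dataclass
class NetParams:
    """Weights and biases of a fully-connected sigmoid network.

    ``weights[l]`` maps activations of layer ``l`` to pre-activations of layer
    ``l + 1`` (shape ``layer_sizes[l+1] x layer_sizes[l]``); ``biases[l]`` has
    length ``layer_sizes[l + 1]``.  There is one weight matrix and one bias
    vector per non-input layer.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        self.validate()

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[1]] + [w.shape[0] for w in self.weights]

    @property
    def n_layers(self) -> int:
        """Number of layers including the input layer."""
        return len(self.weights) + 1

    def validate(self) -> None:
        if len(self.weights) == 0:
            raise ValueError("network needs at least one weight layer")
        if len(self.weights) != len(self.biases):
            raise ValueError(
                f"{len(self.weights)} weight matrices but {len(self.biases)} bias vectors"
            )
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2:
                raise ValueError(f"weight {l} is not a matrix")
            if b.shape != (w.shape[0],):
                raise ValueError(
                    f"bias {l} has length {b.shape}, expected ({w.shape[0]},)"
                )
            if l > 0 and w.shape[1] != self.weights[l - 1].shape[0]:
                raise ValueError(
                    f"layer {l}: weight expects {w.shape[1]} inputs but previous "
                    f"layer has {self.weights[l - 1].shape[0]} units"
                )
        for l, w in enumerate(self.weights):
            if not np.all(np.isfinite(w)) or not np.all(np.isfinite(self.biases[l])):
                raise ValueError(f"non-finite parameter in layer {l}")

    def copy(self) -> "NetParams":
        return NetParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetParams):
            return NotImplemented
        return (
            len(self.weights) == len(other.weights)
            and all(np.array_equal(a, b) for a, b in zip(self.weights, other.weights))
            and all(np.array_equal(a, b) for a, b in zip(self.biases, other.biases))
        )


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the per-sample SGD update rule.

    Defaults are the constants of the reference training recipe: initial
    learning rate 0.4 decayed by 0.99 per epoch, L1 coefficient 4e-7,
    momentum 0.025, noise scale 0.5 * sqrt(2 * eta), 200 epochs of per-sample
    updates, 5 fine-tuning passes, and uniform initialization on
    [-0.03, 0.03].

    ``noise_enabled`` defaults to False: at the stated coefficient the
    injected noise acts as a constant-temperature Langevin bath whose
    temperature exceeds the attainable loss range of networks at this scale,
    so gradient information cannot accumulate (see the methods note).  The
    injection is fully implemented and can be switched on.
    """

    eta0: float = 0.4
    decay: float = 0.99
    lambda_l1: float = 4e-7
    alpha: float = 0.025
    noise_coeff: float = 0.5
    epochs: int = 200
    finetune_passes: int = 5
    init_range: float = 0.03
    seed: int = 0
    noise_enabled: bool = False

    def __post_init__(self) -> None:
        if self.eta0 <= 0:
            raise ValueError("eta0 must be positive")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must be in (0, 1]")
        if self.lambda_l1 < 0 or self.alpha < 0:
            raise ValueError("lambda_l1 and alpha must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.init_range <= 0:
            raise ValueError("init_range must be positive")

    def with_(self, **kwargs) -> "TrainConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class GradState:
    """Mutable optimizer state: previous realized step and the epoch counter."""

    prev_dw: list[np.ndarray]
    prev_db: list[np.ndarray]
    iteration: int = 0

    @classmethod
    def zeros_like(cls, params: NetParams) -> "GradState":
        return cls(
            prev_dw=[np.zeros_like(w) for w in params.weights],
            prev_db=[np.zeros_like(b) for b in params.biases],
        )


def init_params(
    layer_sizes: Sequence[int], init_range: float = 0.03, rng: np.random.Generator | None = None
) -> NetParams:
    """Uniform random initialization on [-init_range, init_range] for all
    weights and biases."""
    rng = np.random.default_rng() if rng is None else rng
    sizes = list(layer_sizes)
    if any(s <= 0 for s in sizes) or len(sizes) < 2:
        raise ValueError(f"invalid layer sizes {sizes}")
    weights = [
        rng.uniform(-init_range, init_range, size=(sizes[l + 1], sizes[l]))
        for l in range(len(sizes) - 1)
    ]
    biases = [
        rng.uniform(-init_range, init_range, size=sizes[l + 1]) for l in range(len(sizes) - 1)
    ]
    return NetParams(weights, biases)


def glorot_init(
    layer_sizes: Sequence[int], rng: np.random.Generator | None = None
) -> NetParams:
    """Fan-scaled uniform initialization: layer l weights on
    [-sqrt(6/(fan_in+fan_out)), +], biases zero.

    Appropriate for networks trained end to end from a cold start, where a
    fixed narrow range leaves deep sigmoid layers on a vanishing-gradient
    plateau; greedily pretrained parts do not need it.
    """
    rng = np.random.default_rng() if rng is None else rng
    sizes = list(layer_sizes)
    if any(s <= 0 for s in sizes) or len(sizes) < 2:
        raise ValueError(f"invalid layer sizes {sizes}")
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        r = np.sqrt(6.0 / (sizes[l] + sizes[l + 1]))
        weights.append(rng.uniform(-r, r, size=(sizes[l + 1], sizes[l])))
        biases.append(np.zeros(sizes[l + 1]))
    return NetParams(weights, biases)


def forward(params: NetParams, x: np.ndarray) -> list[np.ndarray]:
    """Forward pass; returns activations of every layer, input first.

    The input layer is passed through unchanged; every subsequent layer
    applies the logistic function to an affine map, so all non-input
    activations lie strictly in (0, 1).  Accepts a single vector or a batch
    of row vectors.
    """
    x = np.asarray(x, dtype=float)
    n_in = params.weights[0].shape[1]
    if x.shape[-1] != n_in:
        raise ValueError(
            f"layer 0: input has {x.shape[-1]} features, network expects {n_in}"
        )
    activations = [x]
    a = x
    for w, b in zip(params.weights, params.biases):
        a = expit(a @ w.T + b)
        activations.append(a)
    return activations


def l1_penalty(params: NetParams, lambda_l1: float) -> float:
    """Lasso penalty: lambda times the sum of |w| over all weights and biases."""
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be nonnegative")
    total = sum(np.abs(w).sum() for w in params.weights)
    total += sum(np.abs(b).sum() for b in params.biases)
    return float(lambda_l1 * total)


def sample_loss(
    y: np.ndarray, target: np.ndarray, params: NetParams, lambda_l1: float
) -> float:
    """Per-sample loss: squared-error sum over outputs plus the L1 penalty."""
    y = np.asarray(y, dtype=float)
    target = np.asarray(target, dtype=float)
    if y.shape != target.shape:
        raise ValueError(f"output shape {y.shape} != target shape {target.shape}")
    return float(((y - target) ** 2).sum()) + l1_penalty(params, lambda_l1)


def backprop(
    params: NetParams,
    x: np.ndarray,
    target: np.ndarray,
    lambda_l1: float,
    activations: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradient of the per-sample loss for every weight and bias.

    The L1 subgradient at zero is taken as zero.  Returns (weight gradients,
    bias gradients) shaped like the parameters.  ``activations`` may be passed
    to reuse a forward pass already computed for this sample.
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    if activations is None:
        activations = forward(params, x)
    y = activations[-1]
    if y.shape != target.shape:
        raise ValueError(f"output shape {y.shape} != target shape {target.shape}")

    n_wl = len(params.weights)
    gw: list[np.ndarray] = [None] * n_wl  # type: ignore[list-item]
    gb: list[np.ndarray] = [None] * n_wl  # type: ignore[list-item]
    # delta_l = dE/d(pre-activation of layer l+1)
    delta = 2.0 * (y - target) * y * (1.0 - y)
    for l in range(n_wl - 1, -1, -1):
        gw[l] = np.outer(delta, activations[l])
        gb[l] = delta.copy()
        if l > 0:
            a = activations[l]
            delta = (params.weights[l].T @ delta) * a * (1.0 - a)
    if lambda_l1 > 0:
        for l in range(n_wl):
            gw[l] += lambda_l1 * np.sign(params.weights[l])
            gb[l] += lambda_l1 * np.sign(params.biases[l])
    return gw, gb


def lr_schedule(t: int, config: TrainConfig) -> float:
    """Learning rate at epoch t: eta0 * decay**t (constant within an epoch)."""
    if t < 0:
        raise ValueError("epoch index must be nonnegative")
    return config.eta0 * config.decay**t


def sgd_step(
    params: NetParams,
    grads: tuple[list[np.ndarray], list[np.ndarray]],
    state: GradState,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[NetParams, GradState]:
    """One parameter update; mutates ``params`` and ``state`` in place.

    Applies ``-eta * grad + alpha * prev_step (+ noise)`` to every weight and
    bias, with eta from the epoch-indexed schedule and noise drawn i.i.d.
    Normal(0, noise_coeff * sqrt(2 * eta)) when enabled.  ``state.prev_*`` is
    set to the realized step so the next call's momentum term sees it.
    """
    gw, gb = grads
    eta = lr_schedule(state.iteration, config)
    use_noise = config.noise_enabled and config.noise_coeff > 0
    if use_noise and rng is None:
        raise ValueError("noise injection requires an rng")
    sd = config.noise_coeff * np.sqrt(2.0 * eta) if use_noise else 0.0
    for l in range(len(params.weights)):
        dw = -eta * gw[l] + config.alpha * state.prev_dw[l]
        db = -eta * gb[l] + config.alpha * state.prev_db[l]
        if use_noise:
            dw += rng.normal(0.0, sd, size=dw.shape)
            db += rng.normal(0.0, sd, size=db.shape)
        params.weights[l] += dw
        params.biases[l] += db
        state.prev_dw[l] = dw
        state.prev_db[l] = db
    return params, state


def train_net(
    params: NetParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    epochs: int | None = None,
    start_epoch: int = 0,
) -> list[float]:
    """Per-sample SGD over the training set; mutates ``params`` in place.

    Each epoch visits every sample once in a freshly shuffled order.  The
    learning rate is constant within an epoch and decays geometrically across
    epochs starting from ``start_epoch``.  Returns the mean per-sample loss of
    each epoch (evaluated before each sample's update).
    """
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if inputs.ndim != 2 or targets.ndim != 2:
        raise ValueError("inputs and targets must be 2-D (samples x features)")
    if inputs.shape[0] != targets.shape[0]:
        raise ValueError(
            f"{inputs.shape[0]} input rows but {targets.shape[0]} target rows"
        )
    if inputs.shape[0] == 0:
        raise ValueError("empty training set")
    n_epochs = config.epochs if epochs is None else epochs
    state = GradState.zeros_like(params)
    lam = config.lambda_l1
    log: list[float] = []
    for epoch in range(n_epochs):
        state.iteration = start_epoch + epoch
        order = rng.permutation(inputs.shape[0])
        total = 0.0
        for i in order:
            acts = forward(params, inputs[i])
            total += sample_loss(acts[-1], targets[i], params, lam)
            grads = backprop(params, inputs[i], targets[i], lam, activations=acts)
            sgd_step(params, grads, state, config, rng)
        log.append(total / inputs.shape[0])
    return log


# ---------------------------------------------------------------------------
# serialization: portable JSON schema (layer sizes + flat arrays)

_SCHEMA_VERSION = 1


def params_to_dict(params: NetParams) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "layer_sizes": params.layer_sizes,
        "weights": [w.ravel().tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }


def params_from_dict(d: dict) -> NetParams:
    if d.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {d.get('schema_version')}")
    sizes = d["layer_sizes"]
    weights = [
        np.asarray(flat, dtype=float).reshape(sizes[l + 1], sizes[l])
        for l, flat in enumerate(d["weights"])
    ]
    biases = [np.asarray(b, dtype=float) for b in d["biases"]]
    return NetParams(weights, biases)


def save_params(params: NetParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params)))


def load_params(path: str | Path) -> NetParams:
    return params_from_dict(json.loads(Path(path).read_text()))
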