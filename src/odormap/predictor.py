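"""The nine-layer spectrum-to-sensory model.

The predictor is assembled from three separately trained parts: the encoder
half of a spectrum autoencoder, a multilayer-perceptron mapper between the
two latent spaces, and the decoder half of a sensory autoencoder.  Assembly
is pure rewiring — at assembly time the stacked network computes exactly
decode(map(encode(x))) — after which the whole stack is fine-tuned end to
end on (spectrum, sensory) pairs for a few passes.

Default unit counts per layer: 212, 85, 45, 50, 55, 50, 30, 65, 144.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autoencoder import AEModel
from .core_net import (
    NetParams,
    TrainConfig,
    forward,
    glorot_init,
    init_params,
    train_net,
)

__all__ = [
    "MapperModel",
    "NineLayerModel",
    "DEFAULT_MAPPER_HIDDEN",
    "DEFAULT_NINE_LAYER_SIZES",
    "train_mapper",
    "assemble_nine_layer",
    "finetune_full",
    "predict",
]

#: Hidden widths of the latent-space mapper (K_p1, K_p2, K_p3).
DEFAULT_MAPPER_HIDDEN = (50, 55, 50)

#: Unit counts of the assembled model with the default autoencoder shapes.
DEFAULT_NINE_LAYER_SIZES = [212, 85, 45, 50, 55, 50, 30, 65, 144]


@dataclass
class MapperModel:
    """Five-layer perceptron from spectrum codes to sensory codes."""

    params: NetParams
    training_log: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.params.layer_sizes[0]

    @property
    def output_dim(self) -> int:
        return self.params.layer_sizes[-1]


@dataclass
class NineLayerModel:
    """The assembled spectrum -> sensory network plus part provenance."""

    params: NetParams
    provenance: dict = field(default_factory=dict)

    @property
    def layer_sizes(self) -> list[int]:
        return self.params.layer_sizes


def train_mapper(
    spec_codes: np.ndarray,
    sens_codes: np.ndarray,
    config: TrainConfig,
    hidden: tuple[int, int, int] = DEFAULT_MAPPER_HIDDEN,
    rng: np.random.Generator | None = None,
    epochs: int | None = None,
    init: str | float = "glorot",
) -> MapperModel:
    """Supervised training of the latent-space mapper.

    Inputs are spectrum bottleneck codes, targets the matching sensory codes
    (both in (0, 1), one row per sample).  Unlike the autoencoders, the
    mapper gets no greedy pretraining, so by default its weights use
    fan-scaled (Glorot) initialization — with a fixed narrow range a
    three-hidden-layer sigmoid net starts on a vanishing-gradient plateau it
    often fails to leave.  Pass ``init=<float>`` for a uniform half-width
    instead.
    """
    spec_codes = np.asarray(spec_codes, dtype=float)
    sens_codes = np.asarray(sens_codes, dtype=float)
    if spec_codes.shape[0] != sens_codes.shape[0]:
        raise ValueError(
            f"{spec_codes.shape[0]} spectrum-code rows but "
            f"{sens_codes.shape[0]} sensory-code rows"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sizes = [spec_codes.shape[1], *hidden, sens_codes.shape[1]]
    if init == "glorot":
        params = glorot_init(sizes, rng)
    else:
        params = init_params(sizes, float(init), rng)
    log = train_net(params, spec_codes, sens_codes, config, rng, epochs=epochs)
    return MapperModel(params=params, training_log=log)


def assemble_nine_layer(
    spec_ae: AEModel, mapper: MapperModel, sens_ae: AEModel
) -> NineLayerModel:
    """Connect spectrum encoder, mapper and sensory decoder into one stack.

    The weight layers are, in order: the two encoder layers of the spectrum
    autoencoder, the four mapper layers, and the two decoder layers of the
    sensory autoencoder.  Assembly copies weights, so predict() on the result
    is bit-identical to running the three parts in sequence.
    """
    if spec_ae.code_dim != mapper.input_dim:
        raise ValueError(
            f"spectrum-code/mapper joint mismatch: encoder produces "
            f"{spec_ae.code_dim}-dim codes but mapper expects {mapper.input_dim}"
        )
    if mapper.output_dim != sens_ae.code_dim:
        raise ValueError(
            f"mapper/sensory-code joint mismatch: mapper produces "
            f"{mapper.output_dim}-dim codes but decoder expects {sens_ae.code_dim}"
        )
    weights = (
        [w.copy() for w in spec_ae.params.weights[:2]]
        + [w.copy() for w in mapper.params.weights]
        + [w.copy() for w in sens_ae.params.weights[2:]]
    )
    biases = (
        [b.copy() for b in spec_ae.params.biases[:2]]
        + [b.copy() for b in mapper.params.biases]
        + [b.copy() for b in sens_ae.params.biases[2:]]
    )
    provenance = {
        "spectrum_ae": spec_ae.architecture.layer_sizes,
        "mapper": mapper.params.layer_sizes,
        "sensory_ae": sens_ae.architecture.layer_sizes,
    }
    return NineLayerModel(params=NetParams(weights, biases), provenance=provenance)


def finetune_full(
    model: NineLayerModel,
    spectra: np.ndarray,
    sensory: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    passes: int | None = None,
    lr_reset: bool = False,
    pretrain_epochs: int | None = None,
) -> NineLayerModel:
    """End-to-end fine-tuning of the assembled model; few passes by default.

    The learning-rate schedule continues from the epoch budget already
    spent building the parts — three pretraining phases (two greedy stages
    plus end-to-end autoencoder training), i.e. ``3 * config.epochs`` unless
    ``pretrain_epochs`` overrides it — so the few fine-tuning passes run at
    the heavily decayed tail rate and make small corrections.
    ``lr_reset=True`` restarts the schedule at the initial rate instead; in
    practice full-rate (or even quarter-rate) per-sample steps through
    eight stacked weight layers diverge and wreck an assembled solution,
    which is why the continued schedule is the default.  Mutates the model
    in place; zero passes is a no-op.
    """
    n_passes = config.finetune_passes if passes is None else passes
    if n_passes == 0:
        return model
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if lr_reset:
        start = 0
    else:
        start = 3 * config.epochs if pretrain_epochs is None else pretrain_epochs
    train_net(
        model.params,
        np.asarray(spectra, dtype=float),
        np.asarray(sensory, dtype=float),
        config,
        rng,
        epochs=n_passes,
        start_epoch=start,
    )
    return model


def predict(model: NineLayerModel, spectrum: np.ndarray) -> np.ndarray:
    """Sensory-profile prediction for one spectrum or a batch of rows.

    Output entries are sigmoid activations, strictly inside (0, 1).
    """
    return forward(model.params, np.asarray(spectrum, dtype=float))[-1]
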