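"""Synthetic paired spectrum/sensory datasets with a known latent link.

The real use case pairs electron-ionization mass spectra with panel-scored
odor-descriptor profiles; neither dataset is redistributable, so this module
fabricates datasets of the same shape and character for testing and
benchmarking.  A low-dimensional latent vector ``z`` drives both sides:

* **spectra** — a fixed dictionary of fragment channels at random integer m/z
  positions; each channel's intensity is a log-linear function of ``z`` with
  multiplicative lognormal noise, giving sparse nonnegative patterns whose
  global maximum is 1 after normalization (a handful of dominant peaks per
  sample, like a 70 eV EI spectrum);
* **sensory** — a bounded profile ``g(z)`` per descriptor, where ``g`` is
  selected by the ``nonlinearity`` tag: a ``linear`` map (useful as a PLS
  sanity case — with zero noise the spectrum-to-sensory relation is exactly
  linear), a ``sigmoid-mixture`` (the default; a sum of saturating ridge
  functions, so linear models face a real handicap), or an ``rbf`` mixture.
  Gaussian noise is added, values are clipped to [0, 1] and max-normalized.

The generator returns the ground truth (``z`` and the link internals) so
recovery checks can compare against it.  Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_io import SensoryMatrix, SpectrumMatrix, normalize_max

__all__ = ["SynthConfig", "gen_dataset", "gen_toy_fixture", "curved_manifold"]


@dataclass(frozen=True)
class SynthConfig:
    """Shapes and knobs of the generator; defaults mirror the target study
    scale: 121 samples, 212 m/z bins, 144 descriptors, a 3-D latent space,
    roughly 10 dominant peaks per spectrum and descriptor noise of 0.05 on
    the [0, 1] scale."""

    n_samples: int = 121
    n_mz_bins: int = 212
    n_descriptors: int = 144
    latent_dim: int = 3
    peaks_per_spectrum: int = 10
    nonlinearity: str = "sigmoid-mixture"
    noise_sd: float = 0.05
    outlier_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_samples, self.n_mz_bins, self.n_descriptors,
            self.latent_dim, self.peaks_per_spectrum,
        ) < 1:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.nonlinearity not in ("linear", "sigmoid-mixture", "rbf"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


def _spectra_from_latent(
    z: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    n_channels = min(cfg.n_mz_bins, 4 * cfg.peaks_per_spectrum)
    positions = rng.choice(cfg.n_mz_bins, size=n_channels, replace=False)
    w = rng.normal(size=(cfg.latent_dim, n_channels))
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    values = np.zeros((z.shape[0], cfg.n_mz_bins))
    if cfg.nonlinearity == "linear":
        # keep the whole pipeline linear in z: affine channel intensities
        # offset far enough above zero to stay positive, no per-spectrum
        # rescaling (which would be nonlinear)
        a = rng.normal(size=n_channels)
        base = 4.0 * (np.abs(a) + 0.5)
        raw = base + (z @ w) * a
        raw = np.clip(raw, 0.0, None)
    else:
        offsets = rng.normal(-1.0, 1.5, size=n_channels)
        raw = np.exp(1.5 * (z @ w) + offsets)
    if cfg.noise_sd > 0:
        raw = raw * np.exp(cfg.noise_sd * rng.normal(size=raw.shape))
    if cfg.nonlinearity != "linear":
        # EI libraries store relative abundances: base peak scaled to 999
        # per spectrum, so every sample survives dataset-level normalization
        raw = 999.0 * raw / raw.max(axis=1, keepdims=True)
    values[:, positions] = raw
    return values


def _sensory_from_latent(
    z: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    n, d = z.shape[0], cfg.n_descriptors
    if cfg.nonlinearity == "linear":
        beta = rng.normal(size=(cfg.latent_dim, d))
        beta /= np.linalg.norm(beta, axis=0, keepdims=True)
        y = 0.5 + (z @ beta) / 10.0
        link = {"beta": beta}
    elif cfg.nonlinearity == "sigmoid-mixture":
        # steep ridge features make the map strongly nonlinear (hard for a
        # linear model); the negative descriptor offsets keep applicability
        # values concentrated at low-to-mid range, as panel data are
        n_hidden = 8
        u = rng.normal(size=(cfg.latent_dim, n_hidden))
        u /= np.linalg.norm(u, axis=0, keepdims=True)
        t = rng.normal(size=n_hidden)
        h = expit(6.0 * (z @ u) + t)
        v = rng.normal(size=(n_hidden, d))
        c = rng.normal(-0.8, 0.5, size=d)
        y = expit(1.5 * ((h - 0.5) @ v) + c)
        link = {"u": u, "t": t, "v": v, "c": c}
    else:  # rbf
        n_centers = 8
        mu = rng.normal(size=(n_centers, cfg.latent_dim))
        amp = rng.normal(size=(n_centers, d))
        phi = np.exp(-0.5 * ((z[:, None, :] - mu[None]) ** 2).sum(-1))
        raw = phi @ amp
        y = expit(2.0 * raw)
        link = {"mu": mu, "amp": amp}
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.shape)
    return np.clip(y, 0.0, 1.0), link


def gen_dataset(
    cfg: SynthConfig,
) -> tuple[SpectrumMatrix, SensoryMatrix, dict]:
    """Generate a paired (spectra, sensory, ground-truth) dataset.

    Deterministic for a given config.  Ground truth carries the latent
    coordinates, the nonlinearity tag and the link parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    z = rng.normal(size=(cfg.n_samples, cfg.latent_dim))
    if cfg.outlier_frac > 0:
        n_out = int(np.ceil(cfg.outlier_frac * cfg.n_samples))
        idx = rng.choice(cfg.n_samples, size=n_out, replace=False)
        z[idx] *= 3.0
    else:
        idx = np.array([], dtype=int)
    spec_values = _spectra_from_latent(z, cfg, rng)
    sens_values, link = _sensory_from_latent(z, cfg, rng)
    ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    spectra = SpectrumMatrix(
        ids=ids,
        mz_range=(51, 51 + cfg.n_mz_bins - 1),
        values=normalize_max(spec_values),
    )
    sensory = SensoryMatrix(
        ids=ids,
        descriptor_names=[f"D{j + 1:03d}" for j in range(cfg.n_descriptors)],
        values=normalize_max(sens_values),
    )
    truth = {
        "z": z,
        "nonlinearity": cfg.nonlinearity,
        "link": link,
        "outlier_idx": idx,
    }
    return spectra, sensory, truth


def curved_manifold(
    n_samples: int,
    ambient_dim: int = 20,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Points near a curved one-dimensional arc embedded in ``ambient_dim``-D.

    The arc is three quarters of a circle mixed into the ambient space by a
    random rotation, then squashed into [0, 1].  Its intrinsic dimension is 1
    but no single linear direction captures it, so a one-component linear
    projection has irreducible reconstruction error while a one-code
    nonlinear autoencoder does not.
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.5 * np.pi, size=n_samples)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    basis, _ = np.linalg.qr(rng.normal(size=(ambient_dim, 2)))
    x = circle @ basis.T
    x = x + noise_sd * rng.normal(size=x.shape)
    return 0.5 + 0.4 * x / np.abs(x).max()


def gen_toy_fixture() -> tuple[SpectrumMatrix, SensoryMatrix]:
    """Tiny fixed dataset (8 samples, 10 m/z bins, 5 descriptors).

    Values are hand-checkable constants; both matrices are max-normalized so
    their global maximum is exactly 1.
    """
    spec_raw = np.array(
        [
            [0, 8, 0, 2, 0, 0, 1, 0, 0, 0],
            [4, 0, 0, 0, 6, 0, 0, 0, 2, 0],
            [0, 0, 10, 0, 0, 3, 0, 0, 0, 1],
            [1, 0, 0, 5, 0, 0, 0, 4, 0, 0],
            [0, 2, 0, 0, 0, 7, 0, 0, 3, 0],
            [6, 0, 1, 0, 0, 0, 5, 0, 0, 0],
            [0, 0, 0, 3, 8, 0, 0, 2, 0, 0],
            [0, 4, 0, 0, 0, 0, 0, 6, 0, 5],
        ],
        dtype=float,
    )
    sens_raw = np.array(
        [
            [4, 0, 1, 2, 0],
            [0, 3, 0, 0, 2],
            [1, 0, 5, 0, 0],
            [2, 2, 0, 3, 0],
            [0, 1, 2, 0, 4],
            [3, 0, 0, 1, 1],
            [0, 4, 1, 0, 0],
            [1, 0, 0, 4, 2],
        ],
        dtype=float,
    )
    ids = [f"T{i + 1}" for i in range(8)]
    spectra = SpectrumMatrix(
        ids=ids, mz_range=(51, 60), values=normalize_max(spec_raw)
    )
    sensory = SensoryMatrix(
        ids=ids,
        descriptor_names=["floral", "sweet", "burnt", "fruity", "pungent"],
        values=normalize_max(sens_raw),
    )
    return spectra, sensory
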