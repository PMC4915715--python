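"""Cross-validated evaluation of the pipeline and its linear baselines.

The evaluation protocol is repeated k-fold cross-validation (defaults: 6
folds, 10 repetitions, hence 60 fits).  For every fit the full pipeline —
pretrain both autoencoders on the training folds, train the latent mapper,
assemble the nine-layer model, fine-tune — is run from scratch, the held-out
fold is predicted, and a single Pearson correlation is computed over all
descriptor x sample points of that fold pooled together.  Medians across the
fits are the headline summaries: stochastic fits occasionally fail to
converge, and the median is insensitive to such anomalies (failed fits are
additionally excluded and counted).

Baselines: PCA reconstruction error at a matched component count (against
the autoencoders) and two-block PLS regression scored by the identical CV
rule (against the nine-layer predictor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .autoencoder import (
    AEArchitecture,
    encode,
    finetune_ae5,
    pretrain_ae5,
    reconstruction_error,
)
from .core_net import TrainConfig, l1_penalty
from .data_io import SensoryMatrix, SpectrumMatrix
from .predictor import (
    DEFAULT_MAPPER_HIDDEN,
    NineLayerModel,
    assemble_nine_layer,
    finetune_full,
    predict,
    train_mapper,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "EvalResult",
    "make_cv_plan",
    "run_cv",
    "fit_pipeline",
    "pearson_r",
    "pca_reconstruction_error",
    "pls_baseline",
    "select_pls_components",
    "per_sample_errors",
    "dimension_sweep",
    "default_architecture",
]


@dataclass(frozen=True)
class CVPlan:
    """Fold assignments for repeated k-fold cross-validation.

    ``assignments[r, i]`` is the fold label of sample ``i`` in repetition
    ``r``; every repetition is an independent random partition with fold
    sizes differing by at most one.
    """

    n_samples: int
    k_folds: int
    n_reps: int
    seed: int
    assignments: np.ndarray

    @property
    def n_fits(self) -> int:
        return self.k_folds * self.n_reps

    def fold_indices(self, rep: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train row indices, test row indices) for one repetition x fold."""
        labels = self.assignments[rep]
        test = np.flatnonzero(labels == fold)
        train = np.flatnonzero(labels != fold)
        return train, test


def make_cv_plan(n: int, k: int = 6, reps: int = 10, seed: int = 0) -> CVPlan:
    """Seeded random partitions; fold sizes are floor(n/k) or ceil(n/k)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    base = np.concatenate([np.full(n // k + (f < n % k), f) for f in range(k)])
    assignments = np.stack([rng.permutation(base) for _ in range(reps)])
    return CVPlan(n_samples=n, k_folds=k, n_reps=reps, seed=seed, assignments=assignments)


def pearson_r(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation over all flattened elements of two equal-shape
    matrices (descriptor x sample points pooled into one scatter)."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(pred, truth).statistic)


@dataclass
class EvalResult:
    """Per-fit records and pooled error summaries of one CV campaign."""

    records: pd.DataFrame  # columns: rep, fold, r, gen_error, n_test, converged
    per_descriptor_error: np.ndarray  # N x n_descriptors mean |pred - truth|
    n_samples: int
    n_excluded: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def per_sample_mean_error(self) -> np.ndarray:
        return self.per_descriptor_error.mean(axis=1)

    @property
    def converged(self) -> pd.DataFrame:
        return self.records[self.records["converged"]]

    @property
    def median_r(self) -> float:
        return float(self.converged["r"].median())

    @property
    def mean_r(self) -> float:
        return float(self.converged["r"].mean())


def default_architecture(input_dim: int, role: str = "") -> AEArchitecture:
    """Bottleneck shape scaled from the reference ratios (212 -> 85 -> 45 for
    spectra, 144 -> 65 -> 30 for sensory data)."""
    if role == "spectrum" or input_dim >= 180:
        k, d = 0.40, 0.21
    else:
        k, d = 0.45, 0.21
    return AEArchitecture(
        input_dim,
        max(2, int(round(k * input_dim))),
        max(1, int(round(d * input_dim))),
        role=role,
    )


def _as_array(data) -> np.ndarray:
    if isinstance(data, (SpectrumMatrix, SensoryMatrix)):
        return data.values
    return np.asarray(data, dtype=float)


def fit_pipeline(
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    spec_arch: AEArchitecture | None = None,
    sens_arch: AEArchitecture | None = None,
    mapper_hidden: tuple[int, int, int] = DEFAULT_MAPPER_HIDDEN,
    epochs: int | None = None,
    ae_finetune: bool = True,
    finetune_lr_reset: bool = False,
) -> tuple[NineLayerModel, AEModel, AEModel]:
    """One end-to-end training run of the full pipeline on a training set.

    Pretrains both autoencoders (greedy stages plus optional five-layer
    fine-tuning), trains the latent mapper on the paired codes, assembles the
    nine-layer model and fine-tunes it for ``config.finetune_passes`` epochs.
    ``epochs`` overrides ``config.epochs`` for every stage.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if spec_arch is None:
        spec_arch = default_architecture(x_train.shape[1], role="spectrum")
    if sens_arch is None:
        sens_arch = default_architecture(y_train.shape[1], role="sensory")
    spec_ae = pretrain_ae5(x_train, spec_arch, config, rng, epochs=epochs)
    if ae_finetune:
        finetune_ae5(spec_ae, x_train, config, rng, epochs=epochs)
    sens_ae = pretrain_ae5(y_train, sens_arch, config, rng, epochs=epochs)
    if ae_finetune:
        finetune_ae5(sens_ae, y_train, config, rng, epochs=epochs)
    mapper = train_mapper(
        encode(spec_ae, x_train),
        encode(sens_ae, y_train),
        config,
        hidden=mapper_hidden,
        rng=rng,
        epochs=epochs,
    )
    model = assemble_nine_layer(spec_ae, mapper, sens_ae)
    finetune_full(
        model, x_train, y_train, config, rng=rng, lr_reset=finetune_lr_reset
    )
    return model, spec_ae, sens_ae


def _new_error_accumulators(n: int, d: int) -> tuple[np.ndarray, np.ndarray]:
    return np.zeros((n, d)), np.zeros(n)


def run_cv(
    spectra,
    sensory,
    config: TrainConfig,
    plan: CVPlan,
    spec_arch: AEArchitecture | None = None,
    sens_arch: AEArchitecture | None = None,
    mapper_hidden: tuple[int, int, int] = DEFAULT_MAPPER_HIDDEN,
    epochs: int | None = None,
    ae_finetune: bool = True,
    finetune_lr_reset: bool = False,
    folds: list[int] | None = None,
) -> EvalResult:
    """Repeated k-fold cross-validation of the full pipeline.

    Every repetition x fold trains the whole pipeline from scratch on the
    training folds and scores the held-out fold with the pooled Pearson R and
    the generalization error (the summed per-sample loss over the held-out
    samples).  A fit producing non-finite predictions is recorded as
    non-converged, excluded from medians, and counted.  ``folds`` restricts
    each repetition to a subset of fold labels (all folds by default).
    """
    x = _as_array(spectra)
    y = _as_array(sensory)
    if x.shape[0] != y.shape[0] or x.shape[0] != plan.n_samples:
        raise ValueError("spectra, sensory and plan disagree on sample count")
    fold_list = list(range(plan.k_folds)) if folds is None else list(folds)
    err_sum, err_count = _new_error_accumulators(x.shape[0], y.shape[1])
    rows = []
    n_excluded = 0
    for rep in range(plan.n_reps):
        for fold in fold_list:
            train, test = plan.fold_indices(rep, fold)
            rng = np.random.default_rng(
                np.random.SeedSequence([plan.seed, rep, fold]).generate_state(1)[0]
            )
            model, spec_ae, sens_ae = fit_pipeline(
                x[train], y[train], config, rng,
                spec_arch=spec_arch, sens_arch=sens_arch,
                mapper_hidden=mapper_hidden, epochs=epochs,
                ae_finetune=ae_finetune, finetune_lr_reset=finetune_lr_reset,
            )
            pred = predict(model, x[test])
            ok = bool(np.all(np.isfinite(pred)))
            if ok:
                r = pearson_r(pred, y[test])
                sq = ((pred - y[test]) ** 2).sum()
                gen_error = float(sq + len(test) * l1_penalty(model.params, config.lambda_l1))
                abs_err = np.abs(pred - y[test])
                err_sum[test] += abs_err
                err_count[test] += 1
                rows.append(
                    dict(
                        rep=rep, fold=fold, r=r, gen_error=gen_error,
                        n_test=len(test), converged=True,
                        spec_recon=reconstruction_error(spec_ae, x[test]),
                        sens_recon=reconstruction_error(sens_ae, y[test]),
                    )
                )
            else:
                n_excluded += 1
                logger.warning("non-converged fit at rep=%d fold=%d", rep, fold)
                rows.append(
                    dict(
                        rep=rep, fold=fold, r=np.nan, gen_error=np.nan,
                        n_test=len(test), converged=False,
                        spec_recon=np.nan, sens_recon=np.nan,
                    )
                )
    per_desc = np.divide(
        err_sum, err_count[:, None], out=np.zeros_like(err_sum),
        where=err_count[:, None] > 0,
    )
    return EvalResult(
        records=pd.DataFrame(rows),
        per_descriptor_error=per_desc,
        n_samples=x.shape[0],
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# linear baselines


def pca_reconstruction_error(
    train: np.ndarray, test: np.ndarray, n_components: int
) -> float:
    """Absolute-sum reconstruction error of held-out rows under a PCA fit.

    PCA (mean-centering + SVD) is fitted on the training rows; held-out rows
    are projected on the top components and reconstructed.  Zero components
    reconstructs every row as the training mean.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if n_components < 0 or n_components > min(train.shape):
        raise ValueError(f"n_components={n_components} out of range for {train.shape}")
    if n_components == 0:
        recon = np.tile(train.mean(axis=0), (test.shape[0], 1))
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(train)
        recon = pca.inverse_transform(pca.transform(test))
    return float(np.abs(test - recon).sum())


def pls_baseline(
    spectra,
    sensory,
    n_latent: int,
    plan: CVPlan,
) -> EvalResult:
    """Two-block PLS regression evaluated under the identical CV protocol.

    PLS is deterministic, so the spread across fits comes only from the
    random fold assignments.  ``n_latent`` is the number of latent variables;
    zero reduces to predicting the training mean, for which the pooled
    correlation is undefined (zero variance) and an error is raised.
    """
    x = _as_array(spectra)
    y = _as_array(sensory)
    if x.shape[0] != y.shape[0] or x.shape[0] != plan.n_samples:
        raise ValueError("spectra, sensory and plan disagree on sample count")
    err_sum, err_count = _new_error_accumulators(x.shape[0], y.shape[1])
    rows = []
    for rep in range(plan.n_reps):
        for fold in range(plan.k_folds):
            train, test = plan.fold_indices(rep, fold)
            if n_latent == 0:
                pred = np.tile(y[train].mean(axis=0), (len(test), 1))
            else:
                pls = PLSRegression(n_components=n_latent, scale=False)
                pls.fit(x[train], y[train])
                pred = pls.predict(x[test])
            r = pearson_r(pred, y[test])
            abs_err = np.abs(pred - y[test])
            err_sum[test] += abs_err
            err_count[test] += 1
            rows.append(
                dict(
                    rep=rep, fold=fold, r=r,
                    gen_error=float(((pred - y[test]) ** 2).sum()),
                    n_test=len(test), converged=True,
                )
            )
    per_desc = np.divide(
        err_sum, err_count[:, None], out=np.zeros_like(err_sum),
        where=err_count[:, None] > 0,
    )
    return EvalResult(
        records=pd.DataFrame(rows),
        per_descriptor_error=per_desc,
        n_samples=x.shape[0],
        extra={"n_latent": n_latent},
    )


def select_pls_components(
    spectra, sensory, grid: list[int], plan: CVPlan
) -> tuple[int, pd.DataFrame]:
    """Pick the PLS latent count minimizing the median held-out error.

    Returns the chosen count and a table of (n_latent, median error,
    median R) over the grid — the same CV rule and criteria used for the
    neural model's unit counts.
    """
    if not grid:
        raise ValueError("empty grid")
    rows = []
    for n_latent in grid:
        res = pls_baseline(spectra, sensory, n_latent, plan)
        rows.append(
            dict(
                n_latent=n_latent,
                median_gen_error=float(res.records["gen_error"].median()),
                median_r=res.median_r,
            )
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["median_gen_error"].idxmin(), "n_latent"])
    return best, table


# ---------------------------------------------------------------------------
# error analysis and dimension sweeps


def per_sample_errors(
    result: EvalResult, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample and per-descriptor mean absolute errors plus flagged ids.

    Flags the round(q * N) samples (at least one) with the largest mean
    held-out prediction error — the top 5% of 121 samples is 6.  Returns
    (per-sample vector, per-descriptor matrix, flagged sample indices sorted
    by decreasing error).
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    per_sample = result.per_sample_mean_error
    n_flag = max(1, int(round(q * result.n_samples)))
    order = np.argsort(-per_sample, kind="stable")
    flagged = order[:n_flag]
    if per_sample[flagged].max() == 0:
        flagged = flagged[per_sample[flagged] > 0]
    return per_sample, result.per_descriptor_error, flagged


def dimension_sweep(
    data,
    role: str,
    k_grid: list[int],
    d_grid: list[int],
    config: TrainConfig,
    plan: CVPlan,
    epochs: int | None = None,
    ae_finetune: bool = True,
) -> pd.DataFrame:
    """Held-out reconstruction error over a (K, D) autoencoder grid.

    For every outer width K and code dimension D the five-layer autoencoder
    is pretrained (and optionally fine-tuned) on the training folds of every
    repetition x fold and scored by the absolute-sum error on the held-out
    fold; the median across fits is tabulated.  The returned frame has one
    row per D with the best K (argmin of the median error) and that error;
    the full K x D grid is attached as ``result.attrs["grid"]``.
    """
    if not k_grid or not d_grid:
        raise ValueError("empty grid")
    x = _as_array(data)
    grid = pd.DataFrame(index=pd.Index(d_grid, name="D"), columns=pd.Index(k_grid, name="K"), dtype=float)
    for d in d_grid:
        for k in k_grid:
            arch = AEArchitecture(x.shape[1], k, d, role=role)
            errors = []
            for rep in range(plan.n_reps):
                for fold in range(plan.k_folds):
                    train, test = plan.fold_indices(rep, fold)
                    rng = np.random.default_rng(
                        np.random.SeedSequence([plan.seed, rep, fold, k, d]).generate_state(1)[0]
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model = pretrain_ae5(x[train], arch, config, rng, epochs=epochs)
                        if ae_finetune:
                            finetune_ae5(model, x[train], config, rng, epochs=epochs)
                    errors.append(reconstruction_error(model, x[test]))
            grid.loc[d, k] = float(np.median(errors))
    summary = pd.DataFrame(
        {
            "best_K": [int(grid.columns[np.argmin(grid.loc[d].to_numpy())]) for d in d_grid],
            "error": [float(grid.loc[d].min()) for d in d_grid],
        },
        index=pd.Index(d_grid, name="D"),
    )
    summary.attrs["grid"] = grid
    return summary
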