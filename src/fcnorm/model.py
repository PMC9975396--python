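"""The normative model: feature standardization and the autoencoder.

A model of "normality" is trained exclusively on healthy-control feature
vectors. Each of the 91 connectivity features is z-scored with the training
set's mean and SD (z = (x - mu) / sigma), then a fully connected
autoencoder with layer sizes 91-46-13-46-91 learns to reproduce its input.
Deviation of any subject from the healthy norm is quantified by the
reconstruction error:

    MSE_s = (1/n) * sum_i (yhat_i - y_i)^2          (n = 91 features)

Hidden layers use leaky-ReLU activations with dropout and L2 weight decay;
the output layer is linear because the targets are standardized reals.
Training minimizes mean squared error with Adam. The implementation is
plain numpy with a seeded generator driving weight initialization, dropout
masks and batch shuffling, so training is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StandardizationParams",
    "AutoencoderSpec",
    "TrainedModel",
    "ReconstructionResult",
    "CVReport",
    "DegenerateFeatureError",
    "TrainingDivergedError",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
    "train_autoencoder",
    "reconstruct",
    "mse_per_subject",
    "stratified_folds",
    "cross_validate",
    "normalize_selection_metrics",
]


class DegenerateFeatureError(ValueError):
    """A feature has zero variance in the training set; z-scoring fails."""


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and SD, derived from the training set only.

    The SD is the population SD (divides by n). Fitting on any other set
    than the healthy training set would leak test information into the
    norm, so the pipeline only ever passes training rows here.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise DegenerateFeatureError("sigma entries must be > 0")


def fit_standardizer(train_features: np.ndarray) -> StandardizationParams:
    """Per-feature mean/SD of the healthy training set."""
    x = np.asarray(train_features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 training subjects")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)  # population convention (ddof=0)
    dead = np.flatnonzero(sigma == 0)
    if dead.size:
        raise DegenerateFeatureError(
            f"zero training-set SD for feature(s) {dead.tolist()}"
        )
    return StandardizationParams(mu=mu, sigma=sigma, n_train=x.shape[0])


def apply_standardizer(params: StandardizationParams, features: np.ndarray) -> np.ndarray:
    """Elementwise (x - mu) / sigma; applied to every set of subjects."""
    x = np.asarray(features, dtype=float)
    if x.shape[-1] != params.mu.shape[0]:
        raise ValueError(
            f"feature count {x.shape[-1]} does not match standardizer "
            f"({params.mu.shape[0]})"
        )
    return (x - params.mu) / params.sigma


def invert_standardizer(params: StandardizationParams, z: np.ndarray) -> np.ndarray:
    """Algebraic inverse of :func:`apply_standardizer`."""
    return np.asarray(z, dtype=float) * params.sigma + params.mu


# --------------------------------------------------------------------------
# autoencoder
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training protocol of the normative autoencoder.

    Defaults: three hidden layers (91-46-13-46-91), leaky-ReLU (slope 0.01)
    hidden activations with dropout 0.5 after each, linear output, L2
    penalty 1e-5 on all weight matrices, He fan-in normal initialization,
    MSE loss, 1000 epochs of Adam (lr 5e-4, beta1 0.9, beta2 0.999,
    eps 1e-7), batch size 32.
    """

    layer_sizes: tuple[int, ...] = (91, 46, 13, 46, 91)
    leaky_relu_slope: float = 0.01
    l2_penalty: float = 1e-5
    dropout_rate: float = 0.5
    epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 5e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        if len(sizes) < 3 or sizes[0] != sizes[-1]:
            raise ValueError("layer_sizes must be symmetric about a bottleneck")
        if min(sizes[1:-1]) >= sizes[0]:
            raise ValueError("bottleneck must be narrower than the input")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    def with_(self, **kwargs) -> "AutoencoderSpec":
        return replace(self, **kwargs)


@dataclass
class TrainedModel:
    """Trained weights plus everything needed to score new subjects."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    spec: AutoencoderSpec
    standardizer: StandardizationParams | None
    history: np.ndarray  # per-epoch mean training loss (MSE + L2)

    def forward(self, z: np.ndarray) -> np.ndarray:
        """Deterministic inference pass (dropout disabled)."""
        a = np.asarray(z, dtype=float)
        squeeze = a.ndim == 1
        if squeeze:
            a = a[None, :]
        n_layers = len(self.weights)
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if li < n_layers - 1:  # hidden layers: leaky ReLU
                a = np.where(a > 0, a, self.spec.leaky_relu_slope * a)
        return a[0] if squeeze else a


@dataclass(frozen=True)
class ReconstructionResult:
    """Per-subject reconstruction, absolute difference and MSE_s."""

    reconstruction: np.ndarray  # n_subjects x n_features
    abs_diff: np.ndarray        # |yhat - y|, kept per subject per feature
    mse_s: np.ndarray           # length n_subjects


def _he_init(rng: np.random.Generator, sizes: tuple[int, ...]):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_autoencoder(
    spec: AutoencoderSpec,
    train_features: np.ndarray,
    standardizer: StandardizationParams | None = None,
) -> TrainedModel:
    """Train the normative autoencoder on (already standardized) features.

    Runs exactly ``spec.epochs`` epochs of minibatch Adam; the per-epoch
    mean training loss is recorded. Identical spec (including seed) and
    data reproduce the weights bit-for-bit.
    """
    x = np.asarray(train_features, dtype=float)
    if x.ndim != 2 or x.shape[1] != spec.layer_sizes[0]:
        raise ValueError(
            f"expected n x {spec.layer_sizes[0]} feature matrix, got {x.shape}"
        )
    rng = np.random.default_rng(spec.seed)
    weights, biases = _he_init(rng, spec.layer_sizes)
    n_layers = len(weights)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    slope, drop = spec.leaky_relu_slope, spec.dropout_rate
    lr, b1, b2, eps = (
        spec.learning_rate, spec.adam_beta1, spec.adam_beta2, spec.adam_eps,
    )
    n = x.shape[0]
    keep = 1.0 - drop
    history = np.empty(spec.epochs)
    step = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, spec.batch_size):
            xb = x[order[start:start + spec.batch_size]]
            # forward
            a = xb
            acts = [a]
            preacts = []
            masks = []
            for li in range(n_layers):
                zpre = a @ weights[li] + biases[li]
                preacts.append(zpre)
                if li < n_layers - 1:
                    a = np.where(zpre > 0, zpre, slope * zpre)
                    if drop > 0:
                        mask = (rng.random(a.shape) < keep) / keep
                        a = a * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                else:
                    a = zpre
                acts.append(a)
            resid = a - xb
            mse = float(np.mean(resid ** 2))
            loss = mse + spec.l2_penalty * sum(float(np.sum(w ** 2)) for w in weights)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            epoch_loss += loss
            n_batches += 1
            # backward
            delta = 2.0 * resid / resid.size
            step += 1
            bc1 = 1.0 - b1 ** step
            bc2 = 1.0 - b2 ** step
            grads_w = [None] * n_layers
            grads_b = [None] * n_layers
            for li in range(n_layers - 1, -1, -1):
                grads_w[li] = acts[li].T @ delta + 2.0 * spec.l2_penalty * weights[li]
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ weights[li].T
                    if masks[li - 1] is not None:
                        delta = delta * masks[li - 1]
                    delta = delta * np.where(preacts[li - 1] > 0, 1.0, slope)
            for li in range(n_layers):
                for g, mm, vv, p in (
                    (grads_w[li], m_w, v_w, weights),
                    (grads_b[li], m_b, v_b, biases),
                ):
                    mm[li] = b1 * mm[li] + (1 - b1) * g
                    vv[li] = b2 * vv[li] + (1 - b2) * g ** 2
                    p[li] -= lr * (mm[li] / bc1) / (np.sqrt(vv[li] / bc2) + eps)
        history[epoch] = epoch_loss / n_batches
    return TrainedModel(
        weights=weights, biases=biases, spec=spec,
        standardizer=standardizer, history=history,
    )


def mse_per_subject(residuals: np.ndarray) -> np.ndarray:
    """MSE_s: mean over features of the squared residual, per subject."""
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    return np.mean(r ** 2, axis=1)


def reconstruct(model: TrainedModel, features: np.ndarray) -> ReconstructionResult:
    """Score standardized subjects against the healthy norm.

    Inference applies no dropout. Returns, per subject, the reconstructed
    vector, the absolute-difference vector |yhat - y| (the basis of all
    feature-level localization), and MSE_s.
    """
    z = np.atleast_2d(np.asarray(features, dtype=float))
    yhat = model.forward(z)
    resid = yhat - z
    return ReconstructionResult(
        reconstruction=yhat, abs_diff=np.abs(resid), mse_s=mse_per_subject(resid)
    )


# --------------------------------------------------------------------------
# cross-validation and model selection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CVReport:
    """Per-fold median MSE_s and the two model-selection metrics.

    performance = mean over folds of the median training MSE_s;
    generalization_gap = mean of validation-fold medians minus performance.
    """

    fold_train_median: np.ndarray
    fold_val_median: np.ndarray
    performance: float
    generalization_gap: float


def stratified_folds(
    labels: np.ndarray, fold_count: int, seed: int = 0
) -> np.ndarray:
    """Assign each subject to a validation fold, stratified by label.

    Within each label the (seeded, shuffled) members are dealt round-robin
    across folds, keeping label proportions as similar as the counts allow.
    A label with fewer members than folds triggers a warning and is simply
    dealt to as many folds as it can reach.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if fold_count < 2 or fold_count > n:
        raise ValueError("fold_count must be in [2, n_subjects]")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for lab in _unique_in_order(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < fold_count:
            warnings.warn(
                f"dataset label {lab!r} has {idx.size} subjects for "
                f"{fold_count} folds; best-effort proportional assignment",
                stacklevel=2,
            )
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(idx.size) + offset) % fold_count
        offset += idx.size  # stagger so small labels spread across folds
    return fold_of


def _unique_in_order(values: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in values.tolist():
        seen.setdefault(v, None)
    return list(seen)


def cross_validate(
    spec: AutoencoderSpec,
    train_features: np.ndarray,
    fold_count: int = 10,
    dataset_labels: np.ndarray | None = None,
) -> CVReport:
    """k-fold cross-validation of the autoencoder on the training set.

    Folds are stratified by dataset label (site of origin) so each fold has
    a similar dataset mix; each subject is validated exactly once. Reports
    the per-fold median MSE_s of the training and validation splits, the
    mean of the training medians (reconstruction performance) and the
    train-validation gap of those means (generalization).
    """
    x = np.asarray(train_features, dtype=float)
    if dataset_labels is None:
        dataset_labels = np.zeros(x.shape[0], dtype=int)
    dataset_labels = np.asarray(dataset_labels)
    if dataset_labels.shape[0] != x.shape[0]:
        raise ValueError("dataset_labels must align with training subjects")
    fold_of = stratified_folds(dataset_labels, fold_count, seed=spec.seed)
    train_medians = np.empty(fold_count)
    val_medians = np.empty(fold_count)
    for fold in range(fold_count):
        val_mask = fold_of == fold
        model = train_autoencoder(spec, x[~val_mask])
        train_medians[fold] = float(np.median(reconstruct(model, x[~val_mask]).mse_s))
        val_medians[fold] = float(np.median(reconstruct(model, x[val_mask]).mse_s))
    performance = float(np.mean(train_medians))
    gap = float(np.mean(val_medians)) - performance
    return CVReport(
        fold_train_median=train_medians,
        fold_val_median=val_medians,
        performance=performance,
        generalization_gap=gap,
    )


def normalize_selection_metrics(
    candidates: list[tuple[float, float]],
) -> tuple[np.ndarray, int]:
    """Min-max normalize (performance, gap) across candidate models.

    Each metric is mapped by (x - min) / (max - min) over the candidates;
    a metric that is constant across candidates is set to 0 for all, with a
    warning. Returns the normalized pairs and the index of the candidate
    minimizing their sum — the rule used to pick the model that best
    balances reconstruction performance and generalization.
    """
    arr = np.asarray(candidates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 candidates of (performance, gap)")
    lo = arr.min(axis=0)
    span = arr.max(axis=0) - lo
    norm = np.zeros_like(arr)
    for m in range(2):
        if span[m] == 0:
            warnings.warn(
                f"selection metric {m} identical across candidates; set to 0",
                stacklevel=2,
            )
        else:
            norm[:, m] = (arr[:, m] - lo[m]) / span[m]
    best = int(np.argmin(norm.sum(axis=1)))
    return norm, best
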