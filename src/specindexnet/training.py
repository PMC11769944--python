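"""Losses, dataset splitting, the training loop and evaluation metrics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import autograd.numpy as anp
from autograd import value_and_grad
from autograd.tracer import getval

from . import nn
from . import model as mdl
from .preprocess import SpectralDataset

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass
class LossBundle:
    mse: float
    mask_loss: float
    alpha_mask: float = 0.05
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.mse + self.alpha_mask * self.mask_loss


@dataclass
class TrainConfig:
    batch_size: int = 8
    lr: float = 1e-3
    base_lr: float = 1e-4          # cyclic schedule floor (cycle is triangular)
    cycle_epochs: int = 50
    weight_decay: float = 1e-3
    max_epochs: int = 1000
    eval_every: int = 50
    patience: int = 500
    split: tuple = (0.8, 0.1, 0.1)
    alpha_mask: float = 0.05
    seed: int = 0
    n_runs: int = 3
    # discrete-selection schedule: train with soft alignment rows while the
    # Gumbel temperature anneals tau_start -> tau_end (geometric, per epoch),
    # then switch to hard straight-through selections for the last
    # ``hard_frac`` of epochs so the head calibrates to gathered one-hot
    # features; evaluation is always hard.
    train_hard: bool = False
    tau_start: float = 1.0
    tau_end: float = 0.05
    hard_frac: float = 0.3

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class Metrics:
    r2: float
    rmse: float
    mape: float
    n: int


@dataclass
class ModelState:
    """Trained weights plus the target-standardisation constants.

    Targets are standardised inside the training loop (float32 MSE on raw
    μmol m⁻² s⁻¹ values overflows); predictions are mapped back so the
    public interface always speaks original units.
    """

    params: dict
    config: mdl.ModelConfig
    y_mean: float = 0.0
    y_std: float = 1.0


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse_loss(y, yhat):
    y = anp.asarray(y) if isinstance(y, np.ndarray) else y
    if np.shape(y) != np.shape(yhat):
        raise ValueError("length mismatch between targets and predictions")
    d = y - yhat
    return anp.mean(d * d)


def mask_similarity_loss(inputs, outputs, literal: bool = False):
    """Negative mean cosine similarity between each input spectrum and its
    masked output; −1 means identical shape, 0 orthogonal.

    ``literal=True`` evaluates the printed normalisation (sums of absolute
    values instead of L2 norms), kept for comparison; it does not reach −1
    for identical vectors.
    """
    inputs = anp.reshape(inputs, (np.shape(inputs)[0], -1))
    outputs = anp.reshape(outputs, (np.shape(outputs)[0], -1))
    if np.shape(inputs) != np.shape(outputs):
        raise ValueError("shape mismatch")
    if literal:
        denom = anp.sum(anp.abs(inputs), axis=1) * anp.sum(anp.abs(outputs), axis=1)
    else:
        denom = (anp.sqrt(anp.sum(inputs * inputs, axis=1))
                 * anp.sqrt(anp.sum(outputs * outputs, axis=1)))
    num = anp.sum(inputs * outputs, axis=1)
    if np.any(getval(denom) == 0):
        warnings.warn("zero-norm vector in mask loss; contributes 0")
    cos = num / (denom + 1e-12)
    return -anp.mean(cos)


def total_loss(mse: float, mask_loss: float, alpha_mask: float = 0.05) -> LossBundle:
    return LossBundle(mse=float(mse), mask_loss=float(mask_loss), alpha_mask=alpha_mask)


# ---------------------------------------------------------------------------
# splitting and metrics
# ---------------------------------------------------------------------------

def split_dataset(dataset: SpectralDataset, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Random disjoint train/val/test partition covering every sample."""
    n = len(dataset)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train = dataset.subset(order[:n_train])
    val = dataset.subset(order[n_train : n_train + n_val])
    test = dataset.subset(order[n_train + n_val :])
    return train, val, test


def compute_metrics(y, yhat) -> Metrics:
    """R² = 1 − SSE/SST; RMSE; MAPE as a percentage of the observed value."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 points")
    sse = np.sum((y - yhat) ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        warnings.warn("constant targets; R2 undefined (NaN)")
        r2 = np.nan
    else:
        r2 = 1.0 - sse / sst
    rmse = np.sqrt(sse / y.size)
    nz = y != 0
    if not np.all(nz):
        warnings.warn("zero targets skipped in MAPE")
    mape = 100.0 * np.mean(np.abs((yhat[nz] - y[nz]) / y[nz])) if nz.any() else np.nan
    return Metrics(r2=float(r2), rmse=float(rmse), mape=float(mape), n=int(y.size))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _model_loss(params, config, x, y, alpha_mask, noise_rng, hard=False):
    out = mdl.model_forward(params, config, x, hard=hard, rng=noise_rng, train=True)
    mse = mse_loss(y, out["pred"])
    mask = mask_similarity_loss(out["mask_in"], out["mask_out"])
    return mse + alpha_mask * mask


def save_state(state: ModelState, wavelengths, path) -> None:
    """npz weights + json sidecar (config, wavelength grid, target scaling)."""
    import json

    mdl.save_model(state.params, state.config, wavelengths, str(path))
    sidecar = str(path)
    sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".json") as fh:
        meta = json.load(fh)
    meta["y_mean"] = state.y_mean
    meta["y_std"] = state.y_std
    with open(sidecar + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_state(path) -> tuple[ModelState, np.ndarray]:
    import json

    params, config, wavelengths = mdl.load_model(str(path))
    sidecar = str(path)
    sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".json") as fh:
        meta = json.load(fh)
    state = ModelState(params, config, meta.get("y_mean", 0.0),
                       meta.get("y_std", 1.0))
    return state, wavelengths


def predict(state: ModelState, x: np.ndarray, hard: bool = False) -> np.ndarray:
    """Deterministic evaluation-mode predictions, in original trait units.

    Evaluation defaults to the noise-free *soft* alignment — the limit of the
    training objective — which is deterministic and matches what the weights
    were optimised for.  ``hard=True`` evaluates with one-hot gathers instead
    (the interpretation pathway); band extraction always uses the argmax,
    which is identical under both modes.
    """
    out = mdl.model_forward(state.params, state.config, np.asarray(x, dtype=nn.DTYPE),
                            hard=hard, rng=None, train=False)
    return np.asarray(out["pred"], dtype=float) * state.y_std + state.y_mean


def _clip_grads(grads, max_norm: float):
    from autograd.misc import flatten
    flat, _ = flatten(grads)
    norm = float(np.sqrt(np.sum(flat.astype(np.float64) ** 2)))
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        return nn.tree_map(lambda a: a * scale, grads), norm
    return grads, norm


def train_model(params, model_config: mdl.ModelConfig,
                train_xy: tuple, val_xy: tuple, config: TrainConfig,
                verbose: bool = False):
    """RAdam + triangular cyclic LR; keeps the state with the best validation
    R², evaluated every ``eval_every`` epochs; stops at ``max_epochs`` or
    after ``patience`` epochs without improvement.

    Returns (best params, history list of dicts).
    """
    from dataclasses import replace
    model_config = replace(model_config)     # τ anneals on a private copy

    x_train, y_train = train_xy
    x_val, y_val = val_xy
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty train or validation set")
    x_train = np.asarray(x_train, dtype=nn.DTYPE)
    y_raw = np.asarray(y_train, dtype=float)
    y_mean, y_std = float(y_raw.mean()), float(y_raw.std() + 1e-12)
    y_train = ((y_raw - y_mean) / y_std).astype(nn.DTYPE)

    opt = nn.RAdam(params, lr=config.lr, weight_decay=config.weight_decay)
    loss_grad = value_and_grad(_model_loss)
    rng = np.random.default_rng(config.seed)

    def snapshot():
        # config is copied so the stored temperature is the one this
        # checkpoint was validated at (tau keeps annealing afterwards)
        return ModelState(opt.params, replace(model_config), y_mean, y_std)

    best = {"r2": -np.inf, "state": snapshot(), "epoch": 0}
    history = []
    n = len(x_train)
    n_epochs = config.max_epochs
    soft_epochs = max(int(round(n_epochs * (1.0 - config.hard_frac))), 1)
    for epoch in range(1, config.max_epochs + 1):
        lr = nn.cyclic_lr(epoch - 1, config.base_lr, config.lr, config.cycle_epochs)
        frac = min((epoch - 1) / max(soft_epochs - 1, 1), 1.0)
        tau = float(config.tau_start * (config.tau_end / config.tau_start) ** frac)
        model_config.gumbel_temperature = tau
        hard = config.train_hard or epoch > soft_epochs
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = loss_grad(opt.params, model_config, x_train[idx],
                                    y_train[idx], config.alpha_mask, rng,
                                    hard)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            grads, _ = _clip_grads(grads, max_norm=10.0)
            opt.step(grads, lr=lr)
            epoch_loss += float(loss)
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                  "lr": lr, "val_r2": np.nan, "val_rmse": np.nan, "val_mape": np.nan}

        if epoch % config.eval_every == 0 or epoch == config.max_epochs:
            yhat = predict(snapshot(), x_val)
            m = compute_metrics(y_val, yhat)
            record.update(val_r2=m.r2, val_rmse=m.rmse, val_mape=m.mape)
            if m.r2 > best["r2"]:
                best = {"r2": m.r2, "state": snapshot(), "epoch": epoch}
            if verbose:
                logger.info("epoch %d loss %.4f val R2 %.4f", epoch,
                            record["train_loss"], m.r2)
        history.append(record)
        if epoch - best["epoch"] >= config.patience and best["epoch"] > 0:
            break
    return best["state"], history
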