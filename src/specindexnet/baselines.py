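"""Comparison models — SVR, PLSR, a plain 1-D CNN and an index-form CNN —
plus the benchmark harness that runs every model over preprocessing variants
and seeds and tabulates mean ± sd metrics."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import autograd.numpy as anp
from autograd import value_and_grad
from sklearn.cross_decomposition import PLSRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import nn
from .nn import DTYPE
from .preprocess import PreprocessConfig, SpectralDataset, preprocess_dataset
from .training import TrainConfig, compute_metrics, split_dataset

logger = logging.getLogger(__name__)

PLSR_COMPONENT_GRID = tuple(range(10, 16))      # grid-searched 10..15 inclusive

# the index-core features are wide (channels x segments) and strongly
# correlated, so the readout needs a gentler learning rate than the CNNs
INDICECNN_LR = 1e-3


# ---------------------------------------------------------------------------
# classical models
# ---------------------------------------------------------------------------

def plsr_fit_predict(train_xy, val_xy, test_x,
                     component_grid=PLSR_COMPONENT_GRID):
    """Latent-component regression; the component count is chosen by
    validation R² over the grid.  Returns (test predictions, chosen n)."""
    x_train, y_train = train_xy
    x_val, y_val = val_xy
    max_comp = min(len(x_train) - 1, x_train.shape[1])
    grid = [c for c in component_grid if c <= max_comp]
    if not grid:
        raise ValueError("component grid infeasible for this training size")
    best = (None, -np.inf, None)
    for n_comp in grid:
        m = PLSRegression(n_components=n_comp).fit(x_train, y_train)
        r2 = m.score(x_val, y_val)
        if r2 > best[1]:
            best = (m, r2, n_comp)
    model, _, n_comp = best
    return model.predict(test_x).ravel(), n_comp


def svr_fit_predict(train_xy, test_x, kernel: str = "rbf", c: float = 100.0,
                    epsilon: float = 0.1, gamma="scale"):
    """Epsilon-insensitive kernel regression on standardised inputs."""
    x_train, y_train = train_xy
    scaler = StandardScaler().fit(x_train)
    model = SVR(kernel=kernel, C=c, epsilon=epsilon, gamma=gamma)
    model.fit(scaler.transform(x_train), y_train)
    return model.predict(scaler.transform(test_x))


# ---------------------------------------------------------------------------
# 1-D CNN baseline: avgpool(10,10,2) -> conv(1->50,k5) -> conv(50->50,k5,d2)
# -> flatten -> fc -> fc(1)
# ---------------------------------------------------------------------------

@dataclass
class OneDCnnConfig:
    n_bands: int = 204
    pool_kernel: int = 10
    pool_stride: int = 10
    pool_padding: int = 2
    channels: int = 50
    kernel: int = 5
    fc1_units: int = 400

    def __post_init__(self):
        if not (400 <= self.fc1_units <= 1000):
            raise ValueError("fc1_units must lie in [400, 1000]")

    @property
    def flat_size(self) -> int:
        pooled = (self.n_bands + 2 * self.pool_padding - self.pool_kernel) \
            // self.pool_stride + 1
        after1 = pooled - (self.kernel - 1)
        after2 = after1 - 2 * (self.kernel - 1)
        return self.channels * after2


def onedcnn_init(config: OneDCnnConfig, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    return {
        "conv1": nn.conv_init(rng, 1, config.channels, config.kernel),
        "conv2": nn.conv_init(rng, config.channels, config.channels, config.kernel),
        "fc1": nn.linear_init(rng, config.flat_size, config.fc1_units),
        "fc2": nn.linear_init(rng, config.fc1_units, 1),
    }


def onedcnn_forward(params: dict, config: OneDCnnConfig, x):
    """x: (B, n_bands) -> (B,) predictions."""
    h = anp.reshape(x, (x.shape[0], 1, config.n_bands))
    h = nn.avgpool1d(h, config.pool_kernel, config.pool_stride, config.pool_padding)
    h = nn.relu(nn.conv1d(params["conv1"], h))
    h = nn.relu(nn.conv1d(params["conv2"], h, dilation=2))
    h = anp.reshape(h, (h.shape[0], -1))
    h = nn.relu(nn.linear(params["fc1"], h))
    return anp.reshape(nn.linear(params["fc2"], h), (-1,))


# ---------------------------------------------------------------------------
# index-form CNN: four conv+sigmoid band-feature extractors feeding
# (R1+R2)/(R3*R4) and a linear readout
# ---------------------------------------------------------------------------

@dataclass
class IndiceCnnConfig:
    n_bands: int = 204
    channels: int = 64
    kernel: int = 5
    pool_kernel: int = 10
    pool_stride: int = 10
    pool_padding: int = 2
    eps: float = 1e-6

    @property
    def segments(self) -> int:
        return (self.n_bands + 2 * self.pool_padding - self.pool_kernel) \
            // self.pool_stride + 1


def indicecnn_init(config: IndiceCnnConfig, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    out = nn.linear_init(rng, config.channels * config.segments, 1)
    # zero-init readout: the index core has a large positive offset and a
    # random projection of it stalls the adaptive optimiser for a long time
    out["w"] = np.zeros_like(out["w"])
    return {
        "extractors": [nn.conv_init(rng, 1, config.channels, config.kernel)
                       for _ in range(4)],
        "out": out,
    }


def indicecnn_features(params: dict, config: IndiceCnnConfig, x):
    """Four sigmoid conv+pool region features R1..R4: list of (B, C, segments)."""
    h = anp.reshape(x, (x.shape[0], 1, config.n_bands))
    feats = []
    for p in params["extractors"]:
        f = nn.sigmoid(nn.conv1d(p, h, padding=(config.kernel - 1) // 2))
        feats.append(nn.avgpool1d(f, config.pool_kernel, config.pool_stride,
                                  config.pool_padding))
    return feats


def indicecnn_forward(params: dict, config: IndiceCnnConfig, x):
    r1, r2, r3, r4 = indicecnn_features(params, config, x)
    core = (r1 + r2) / (r3 * r4 + config.eps)
    # pole guard as in the main model, then remove the common-mode offset
    # (the quotient of sigmoids sits near 4, which stalls adaptive training)
    core = anp.clip(core, -50.0, 50.0) - 4.0
    core = anp.reshape(core, (core.shape[0], -1))
    return anp.reshape(nn.linear(params["out"], core), (-1,))


# ---------------------------------------------------------------------------
# tiny shared trainer for the CNN baselines
# ---------------------------------------------------------------------------

def train_cnn(forward, params, train_xy, val_xy, *, epochs: int = 60,
              batch_size: int = 32, lr: float = 1e-3, weight_decay: float = 1e-3,
              seed: int = 0, eval_every: int = 10):
    """RAdam training with standardised targets; keeps the best-validation
    state.  ``forward(params, x)`` must return (B,) predictions."""
    x_train, y_train = train_xy
    x_val, y_val = val_xy
    x_train = np.asarray(x_train, dtype=DTYPE)
    y_mean, y_std = float(np.mean(y_train)), float(np.std(y_train) + 1e-12)
    ys = ((np.asarray(y_train, dtype=float) - y_mean) / y_std).astype(DTYPE)

    def loss(p, xb, yb):
        d = forward(p, xb) - yb
        return anp.mean(d * d)

    lg = value_and_grad(loss)
    opt = nn.RAdam(params, lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    best = (-np.inf, opt.params)
    n = len(x_train)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            idx = order[s : s + batch_size]
            _, grads = lg(opt.params, x_train[idx], ys[idx])
            opt.step(grads)
        if epoch % eval_every == 0 or epoch == epochs:
            pred = np.asarray(forward(opt.params, np.asarray(x_val, dtype=DTYPE)))
            r2 = compute_metrics(y_val, pred * y_std + y_mean).r2
            if r2 > best[0]:
                best = (r2, opt.params)
    final = best[1]
    return final, (lambda x: np.asarray(
        forward(final, np.asarray(x, dtype=DTYPE))) * y_std + y_mean)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    rows: list = field(default_factory=list)    # dicts: model/variant/stats

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.rows, fh, indent=2)

    def cell(self, model: str, variant: str) -> dict:
        for row in self.rows:
            if row["model"] == model and row["variant"] == variant:
                return row
        raise KeyError((model, variant))


PREPROCESS_VARIANTS = {
    "SG": PreprocessConfig(poc_beta=1.0),
    "SG-POC": PreprocessConfig(poc_beta=0.6),
}


def _fit_predict_for(model_name: str, train_xy, val_xy, test_x, seed: int,
                     deep_epochs: int, deep_factory=None):
    n_bands = train_xy[0].shape[1]
    if model_name == "PLSR":
        pred, _ = plsr_fit_predict(train_xy, val_xy, test_x)
        return pred
    if model_name == "SVR":
        return svr_fit_predict(train_xy, test_x)
    if model_name == "OneDCNN":
        cfg = OneDCnnConfig(n_bands=n_bands)
        params = onedcnn_init(cfg, seed=seed)
        _, predict = train_cnn(lambda p, x: onedcnn_forward(p, cfg, x), params,
                               train_xy, val_xy, epochs=deep_epochs, seed=seed)
        return predict(test_x)
    if model_name == "IndiceCNN":
        cfg = IndiceCnnConfig(n_bands=n_bands)
        params = indicecnn_init(cfg, seed=seed)
        _, predict = train_cnn(lambda p, x: indicecnn_forward(p, cfg, x), params,
                               train_xy, val_xy, epochs=deep_epochs, seed=seed,
                               lr=INDICECNN_LR)
        return predict(test_x)
    if deep_factory is not None and model_name == "BandIndexNet":
        return deep_factory(train_xy, val_xy, test_x, seed)
    raise ValueError(f"unknown model {model_name!r}")


def run_benchmark(dataset: SpectralDataset, trait: str = "vcmax",
                  models=("SVR", "PLSR", "OneDCNN", "IndiceCNN"),
                  variants=None, n_runs: int = 3, seed: int = 0,
                  deep_epochs: int = 60, deep_factory=None,
                  split=(0.8, 0.1, 0.1)) -> BenchmarkReport:
    """Each model × preprocessing variant is trained/evaluated on identical
    splits for each of ``n_runs`` seeds; cells report mean ± sd."""
    variants = dict(variants or PREPROCESS_VARIANTS)
    labeled = dataset.labeled(trait)
    report = BenchmarkReport()
    for variant_name, pre_cfg in variants.items():
        pre = preprocess_dataset(labeled, pre_cfg)
        x_all = pre.reflectance_matrix()
        y_all = pre.trait_vector(trait)
        for model_name in models:
            stats = {"r2": [], "rmse": [], "mape": []}
            error = None
            for run in range(n_runs):
                run_seed = seed + run
                tr_i, va_i, te_i = split_dataset(pre, split, seed=run_seed)
                sel = {id(s): i for i, s in enumerate(pre.samples)}
                tr = np.array([sel[id(s)] for s in tr_i.samples])
                va = np.array([sel[id(s)] for s in va_i.samples])
                te = np.array([sel[id(s)] for s in te_i.samples])
                try:
                    pred = _fit_predict_for(
                        model_name, (x_all[tr], y_all[tr]), (x_all[va], y_all[va]),
                        x_all[te], run_seed, deep_epochs, deep_factory)
                    m = compute_metrics(y_all[te], pred)
                    stats["r2"].append(m.r2)
                    stats["rmse"].append(m.rmse)
                    stats["mape"].append(m.mape)
                except Exception as exc:        # record, keep the run going
                    logger.exception("benchmark cell failed")
                    error = str(exc)
            row = {"model": model_name, "variant": variant_name,
                   "trait": trait, "n_runs": len(stats["r2"]), "error": error}
            for key, vals in stats.items():
                row[f"{key}_mean"] = float(np.mean(vals)) if vals else np.nan
                row[f"{key}_sd"] = float(np.std(vals)) if vals else np.nan
            report.rows.append(row)
    return report
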