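"""Canonical experiment protocols shared by the test suite, the acceptance
script and the CLI.

The reference architecture is CPU-heavy, so the experiment runs here use a
narrower *desk-scale* configuration (fewer channels, fewer epochs) with the
same structure; every width/epoch choice lives in one place.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import model as mdl
from . import baselines, interpret, synthetic, training
from .preprocess import PreprocessConfig, preprocess_dataset

PLANTED_WAVELENGTHS = tuple(synthetic.DEFAULT_PLANTED_BANDS.values())   # 800/550/670


def desk_model_config(n_bands: int = 204) -> mdl.ModelConfig:
    """Reduced-width model used for CPU-budget experiments."""
    return mdl.ModelConfig(n_bands=n_bands, gconv_channels=32, ucrn_channels=16,
                           recurrent_hidden=16, attn_channels=16, head_hidden=64,
                           branch_clip=20.0)


def desk_train_config(seed: int, epochs: int = 35) -> training.TrainConfig:
    return training.TrainConfig(batch_size=16, max_epochs=epochs, eval_every=5,
                                patience=epochs, cycle_epochs=40, seed=seed,
                                hard_frac=0.0, tau_end=0.05)


@dataclass
class RunResult:
    seed: int
    state: training.ModelState
    test_r2: float
    test_rmse: float
    top8: list
    planted_hits: int
    form_scores: dict
    plsr_r2: float = np.nan
    split_indices: tuple = field(default=None, repr=False)
    dataset: object = field(default=None, repr=False)


def hits_within(wavelengths, targets=PLANTED_WAVELENGTHS, tol: float = 15.0) -> int:
    return sum(1 for w in wavelengths
               if min(abs(w - t) for t in targets) <= tol)


def planted_link_run(seed: int, n: int = 600, epochs: int = 35,
                     trait: str = "vcmax", resample_bands: int | None = None,
                     with_plsr: bool = False) -> RunResult:
    """Generate data, split 80/10/10, train the band-attention model, and
    summarise held-out accuracy plus interpretation outputs."""
    ds = synthetic.generate_dataset(n, seed=seed)
    if resample_bands is not None:
        ds = preprocess_dataset(ds, PreprocessConfig(resample_bands=resample_bands))
    tr, va, te = training.split_dataset(ds, seed=seed)

    def xy(d):
        return d.reflectance_matrix().astype(np.float32), \
            d.trait_vector(trait).astype(np.float32)

    (x_tr, y_tr), (x_va, y_va), (x_te, y_te) = xy(tr), xy(va), xy(te)
    cfg = desk_model_config(n_bands=ds.band_count)
    params = mdl.init_model(cfg, seed=seed)
    state, _ = training.train_model(params, cfg, (x_tr, y_tr), (x_va, y_va),
                                    desk_train_config(seed, epochs))
    metrics = training.compute_metrics(y_te, training.predict(state, x_te))

    # frequencies aggregated over every held-out spectrum: selections are
    # input-dependent, and per-sample noise averages out of the histogram
    sels = interpret.extract_band_selections(state, ds.wavelengths, probe=x_te)
    report = interpret.band_frequency_report(sels, k=8)
    imp = interpret.index_form_importance(state, x_te)
    plsr_r2 = np.nan
    if with_plsr:
        pred, _ = baselines.plsr_fit_predict((x_tr, y_tr), (x_va, y_va), x_te)
        plsr_r2 = training.compute_metrics(y_te, pred).r2
    return RunResult(
        seed=seed, state=state, test_r2=metrics.r2, test_rmse=metrics.rmse,
        top8=report.top_k, planted_hits=hits_within(report.top_k),
        form_scores=dict(zip(mdl.BRANCH_NAMES, map(float, imp))),
        plsr_r2=float(plsr_r2),
        split_indices=None, dataset=ds,
    )


def deep_vs_plsr_seed(seed: int, run: RunResult, onedcnn_epochs: int = 100,
                      indicecnn_epochs: int = 40, trait: str = "vcmax") -> dict:
    """Train the CNN baselines on the same data/split as ``run`` and compare
    the deep-model group mean R² to PLSR."""
    ds = run.dataset
    tr, va, te = training.split_dataset(ds, seed=seed)

    def xy(d):
        return d.reflectance_matrix().astype(np.float32), d.trait_vector(trait)

    (x_tr, y_tr), (x_va, y_va), (x_te, y_te) = xy(tr), xy(va), xy(te)
    out = {"seed": seed, "attention_net": run.test_r2, "plsr": run.plsr_r2}

    c1 = baselines.OneDCnnConfig(n_bands=ds.band_count)
    p1 = baselines.onedcnn_init(c1, seed=seed)
    _, pred1 = baselines.train_cnn(
        lambda p, x: baselines.onedcnn_forward(p, c1, x), p1,
        (x_tr, y_tr), (x_va, y_va), epochs=onedcnn_epochs, seed=seed)
    out["onedcnn"] = training.compute_metrics(y_te, pred1(x_te)).r2

    c2 = baselines.IndiceCnnConfig(n_bands=ds.band_count)
    p2 = baselines.indicecnn_init(c2, seed=seed)
    _, pred2 = baselines.train_cnn(
        lambda p, x: baselines.indicecnn_forward(p, c2, x), p2,
        (x_tr, y_tr), (x_va, y_va), epochs=indicecnn_epochs, seed=seed,
        lr=baselines.INDICECNN_LR)
    out["indicecnn"] = training.compute_metrics(y_te, pred2(x_te)).r2

    out["deep_mean"] = float(np.mean([out["attention_net"], out["onedcnn"],
                                      out["indicecnn"]]))
    return out
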