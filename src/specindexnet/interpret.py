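"""Interpretation of a trained model: sensitive-band histograms, index-form
importance scores and band-subset export for filtered-band validation."""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import model as mdl
from .preprocess import SpectralDataset
from .training import ModelState


@dataclass
class SensitivityReport:
    band_counts: dict                   # wavelength (nm) -> selection count
    top_k: list                         # wavelengths, descending count
    form_scores: dict = field(default_factory=dict)
    discovered_formula: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def histogram_csv(self, path) -> None:
        items = sorted(self.band_counts.items())
        pd.DataFrame({"wavelength": [k for k, _ in items],
                      "count": [v for _, v in items]}).to_csv(path, index=False)


def extract_band_selections(state: ModelState, wavelengths: np.ndarray,
                            probe: np.ndarray | None = None) -> list[mdl.BandSelection]:
    """Noise-free hard-argmax selections of every head × channel.

    ``probe`` holds the spectrum or spectra (n, n_bands) fed through the
    network to realise the activations; defaults to the flat 0.5 spectrum.
    Multi-row probes yield one selection record per (sample, head, channel),
    aggregating the input-dependent choices.  Deterministic: repeated calls
    give identical selections.
    """
    if state.params is None:
        raise ValueError("untrained state")
    cfg = state.config
    if probe is None:
        probe = np.full((1, cfg.n_bands), 0.5, dtype=np.float32)
    probe = np.asarray(probe, dtype=np.float32).reshape(-1, cfg.n_bands)
    out = mdl.model_forward(state.params, cfg, probe, hard=True, rng=None,
                            train=False)
    return mdl.selections_from_band_idx(out["band_idx"], np.asarray(wavelengths))


def band_frequency_report(selections: list[mdl.BandSelection], k: int = 8) -> SensitivityReport:
    """Histogram of selected wavelengths; top-k by count, ties by wavelength."""
    if not selections:
        raise ValueError("no selections")
    counts = Counter(s.wavelength for s in selections)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    report = SensitivityReport(
        band_counts={float(w): int(c) for w, c in sorted(counts.items())},
        top_k=[float(w) for w, _ in ordered[:k]],
    )
    report.discovered_formula = discovered_formula(selections)
    return report


def discovered_formula(selections: list[mdl.BandSelection]) -> dict:
    """Modal wavelength per branch role — the 'discovered index' summary."""
    out = {}
    for branch in mdl.BRANCH_NAMES:
        roles = {}
        for role in (f"R{i+1}" for i in range(mdl.BRANCH_ROLES[branch])):
            wl = [s.wavelength for s in selections
                  if s.branch == branch and s.role == role]
            if wl:
                roles[role] = float(Counter(wl).most_common(1)[0][0])
        out[branch] = roles
    return out


def index_form_importance(state: ModelState, eval_x: np.ndarray) -> np.ndarray:
    """Mean softmax gate score per index form over samples and positions.

    Returns a 3-vector over (double_diff, add_mul, ratio) summing to 1.
    """
    eval_x = np.asarray(eval_x, dtype=np.float32)
    if eval_x.ndim != 2 or len(eval_x) == 0:
        raise ValueError("empty or malformed evaluation set")
    out = mdl.model_forward(state.params, state.config, eval_x, hard=True,
                            rng=None, train=False)
    scores = np.asarray(out["form_scores"])        # (B, 3, A)
    mean = scores.mean(axis=(0, 2))
    return mean / mean.sum()


def export_band_subset(dataset: SpectralDataset, wavelengths) -> tuple[np.ndarray, np.ndarray]:
    """(n, k) reflectance at the requested wavelengths (nearest band when
    off-grid, with a warning), preserving sample and wavelength order."""
    import warnings

    grid = dataset.wavelengths
    refl = dataset.reflectance_matrix()
    cols = []
    used = []
    for w in wavelengths:
        i = int(np.argmin(np.abs(grid - w)))
        if abs(grid[i] - w) > 1e-6:
            warnings.warn(f"{w} nm off-grid; using nearest band {grid[i]:.1f} nm")
        cols.append(refl[:, i])
        used.append(grid[i])
    return np.stack(cols, axis=1), np.asarray(used)
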