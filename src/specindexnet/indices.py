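"""Classic two-band vegetation indices (SR, mNDVI, SIPI) and exhaustive
λ1×λ2 correlation maps against trait labels."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import SpectralDataset, SpectralSample

EPS = 1e-9

FORMULAS = ("SR", "mNDVI", "SIPI")


@dataclass
class ClassicIndexFormula:
    """SR = Rλ1/Rλ2; mNDVI = (Rref−Rλ1)/(Rref+Rλ2); SIPI = (Rref−Rλ1)/(Rref−Rλ2).

    lambda_ref (default 440 nm, blue) is only used by mNDVI and SIPI.
    """

    name: str
    lambda_ref: Optional[float] = None

    def __post_init__(self):
        if self.name not in FORMULAS:
            raise ValueError(f"unknown index formula {self.name!r}")
        if self.name in ("mNDVI", "SIPI") and self.lambda_ref is None:
            self.lambda_ref = 440.0
        if self.name == "SR":
            self.lambda_ref = None


@dataclass
class CorrelationMap:
    lambda1_grid: np.ndarray
    lambda2_grid: np.ndarray
    rho: np.ndarray
    trait: str
    formula: str

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.rho, index=self.lambda1_grid, columns=self.lambda2_grid)
        df.index.name = "lambda1"
        df.to_csv(path)


def _band_index(wavelengths: np.ndarray, target: float) -> int:
    if target < wavelengths[0] - 1e-9 or target > wavelengths[-1] + 1e-9:
        raise ValueError(f"wavelength {target} nm outside grid span "
                         f"[{wavelengths[0]}, {wavelengths[-1]}]")
    return int(np.argmin(np.abs(wavelengths - target)))


def _index_values(refl: np.ndarray, formula: ClassicIndexFormula,
                  i1, i2, iref) -> np.ndarray:
    """Vectorized index evaluation; refl is (n_samples, n_bands)."""
    r1 = refl[..., i1]
    r2 = refl[..., i2]
    if formula.name == "SR":
        return r1 / (r2 + EPS)
    rref = refl[..., iref]
    if formula.name == "mNDVI":
        return (rref - r1) / (rref + r2 + EPS)
    return (rref - r1) / (rref - r2 + EPS)          # SIPI


def evaluate_classic_index(sample: SpectralSample, formula: ClassicIndexFormula,
                           lambda1: float, lambda2: float) -> float:
    wl = sample.wavelengths
    i1 = _band_index(wl, lambda1)
    i2 = _band_index(wl, lambda2)
    iref = _band_index(wl, formula.lambda_ref) if formula.lambda_ref is not None else None
    return float(_index_values(sample.reflectance, formula, i1, i2, iref))


def correlation_map(dataset: SpectralDataset, trait: str,
                    formula: ClassicIndexFormula, method: str = "pearson") -> CorrelationMap:
    """Correlation between the index at every (λ1, λ2) pair and the trait.

    method: 'pearson' (default) or 'spearman'.  Cells where the index is
    constant across samples are NaN.
    """
    labeled = dataset.labeled(trait)
    if len(labeled) < 3:
        raise ValueError("need at least 3 labeled samples")
    wl = labeled.wavelengths
    refl = labeled.reflectance_matrix()            # (n, B)
    y = labeled.trait_vector(trait)
    n, n_bands = refl.shape

    iref = _band_index(wl, formula.lambda_ref) if formula.lambda_ref is not None else None
    # (n, B, B) cube of index values for every band pair
    r1 = refl[:, :, None]                          # (n, B, 1) -> λ1 axis
    r2 = refl[:, None, :]                          # (n, 1, B) -> λ2 axis
    if formula.name == "SR":
        cube = r1 / (r2 + EPS)
    else:
        rref = refl[:, iref][:, None, None]
        if formula.name == "mNDVI":
            cube = (rref - r1) / (rref + r2 + EPS)
        else:
            cube = (rref - r1) / (rref - r2 + EPS)

    if method == "spearman":
        cube = rankdata(cube, axis=0)
        y = rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")

    xc = cube - cube.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.einsum("nij,n->ij", xc, yc) / (sx * sy)
    rho[~np.isfinite(rho)] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    return CorrelationMap(wl.copy(), wl.copy(), rho, trait, formula.name)


def best_band_pairs(cmap: CorrelationMap, k: int) -> list[tuple[float, float, float]]:
    """k cells of largest |ρ|, descending; ties broken by ascending (λ1, λ2)."""
    finite = np.argwhere(np.isfinite(cmap.rho))
    if finite.size == 0:
        return []
    if len(finite) < k:
        warnings.warn(f"only {len(finite)} finite cells; truncating top-{k} list")
    cells = [(cmap.lambda1_grid[i], cmap.lambda2_grid[j], cmap.rho[i, j])
             for i, j in finite]
    cells.sort(key=lambda c: (-abs(c[2]), c[0], c[1]))
    return [(float(l1), float(l2), float(r)) for l1, l2, r in cells[:k]]


def write_best_pairs_json(pairs, path) -> None:
    with open(path, "w") as fh:
        json.dump([{"lambda1": l1, "lambda2": l2, "rho": r} for l1, l2, r in pairs],
                  fh, indent=2)
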