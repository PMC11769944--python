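"""Spectral dataset containers, CSV I/O and the three preprocessing transforms:
Savitzky-Golay smoothing, power compression and cubic-spline band resampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)


class SpectraFormatError(ValueError):
    """Raised for malformed spectra / trait files."""


@dataclass
class SpectralSample:
    """A single leaf spectrum with optional trait labels.

    wavelengths are nm, strictly increasing; reflectance values lie in [0, 1];
    vcmax / jmax are in μmol m⁻² s⁻¹ when present.
    """

    sample_id: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    vcmax: Optional[float] = None
    jmax: Optional[float] = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise SpectraFormatError(
                f"sample {self.sample_id}: {self.wavelengths.size} wavelengths "
                f"vs {self.reflectance.size} reflectance values"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectraFormatError(f"sample {self.sample_id}: non-finite reflectance")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraFormatError(f"sample {self.sample_id}: wavelengths not strictly increasing")


@dataclass
class SpectralDataset:
    """Ordered collection of samples sharing one wavelength grid."""

    samples: list = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        if self.samples:
            grid = self.samples[0].wavelengths
            for s in self.samples[1:]:
                if s.wavelengths.shape != grid.shape or not np.allclose(s.wavelengths, grid):
                    raise SpectraFormatError("samples do not share a common wavelength grid")

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.samples[0].wavelengths

    @property
    def band_count(self) -> int:
        return self.samples[0].wavelengths.size

    def reflectance_matrix(self) -> np.ndarray:
        return np.stack([s.reflectance for s in self.samples])

    def trait_vector(self, trait: str) -> np.ndarray:
        vals = [getattr(s, trait) for s in self.samples]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)

    def labeled(self, trait: str) -> "SpectralDataset":
        keep = [s for s in self.samples if getattr(s, trait) is not None]
        return SpectralDataset(samples=keep, source=self.source)

    def subset(self, indices: Sequence[int]) -> "SpectralDataset":
        return SpectralDataset(samples=[self.samples[i] for i in indices], source=self.source)


@dataclass
class PreprocessConfig:
    """Savitzky-Golay window/order, power-compression exponent, optional resampling."""

    sg_window: int = 21
    sg_order: int = 2
    poc_beta: float = 1.0
    resample_bands: Optional[int] = None

    def __post_init__(self):
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if not (0.0 < self.poc_beta <= 2.0):
            raise ValueError("poc_beta must lie in (0, 2]")
        if self.resample_bands is not None and self.resample_bands < 4:
            raise ValueError("resample_bands must be >= 4")


# ---------------------------------------------------------------------------
# I/O — spectra CSV: sample_id + R_<nm> columns; traits CSV: sample_id,vcmax,jmax
# ---------------------------------------------------------------------------

def read_spectra_csv(spectra_path, traits_path=None) -> SpectralDataset:
    df = pd.read_csv(spectra_path, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise SpectraFormatError("spectra CSV must have a 'sample_id' column")
    band_cols = [c for c in df.columns if c.startswith("R_")]
    if not band_cols:
        raise SpectraFormatError("no band columns (expected names like 'R_400.0')")
    try:
        wl = np.array([float(c[2:]) for c in band_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"band column names must encode wavelengths: {exc}") from exc
    order = np.argsort(wl)
    wl = wl[order]
    band_cols = [band_cols[i] for i in order]

    refl = df[band_cols].to_numpy()
    if not np.issubdtype(refl.dtype, np.number):
        raise SpectraFormatError("non-numeric reflectance values")
    if np.isnan(refl).any():
        raise SpectraFormatError("missing reflectance values")

    if refl.size and (refl.min() < 0.0 or refl.max() > 1.0):
        logger.warning("reflectance outside [0, 1]; clipping (sensor noise tolerated)")
        refl = np.clip(refl, 0.0, 1.0)

    traits = {}
    if traits_path is not None:
        tdf = pd.read_csv(traits_path)
        for col in ("sample_id", "vcmax", "jmax"):
            if col not in tdf.columns:
                raise SpectraFormatError(f"traits CSV missing column '{col}'")
        for _, row in tdf.iterrows():
            traits[str(row["sample_id"])] = (
                None if pd.isna(row["vcmax"]) else float(row["vcmax"]),
                None if pd.isna(row["jmax"]) else float(row["jmax"]),
            )

    samples = []
    for i, sid in enumerate(df["sample_id"].astype(str)):
        vc, jm = traits.get(sid, (None, None))
        samples.append(SpectralSample(sid, wl, refl[i], vcmax=vc, jmax=jm))
    return SpectralDataset(samples=samples, source=str(spectra_path))


def write_spectra_csv(dataset: SpectralDataset, spectra_path, traits_path=None) -> None:
    wl = dataset.wavelengths
    cols = {"sample_id": [s.sample_id for s in dataset]}
    refl = dataset.reflectance_matrix()
    for j, w in enumerate(wl):
        cols[f"R_{w:g}"] = refl[:, j]
    pd.DataFrame(cols).to_csv(spectra_path, index=False, float_format="%.17g")
    if traits_path is not None:
        pd.DataFrame({
            "sample_id": [s.sample_id for s in dataset],
            "vcmax": [s.vcmax for s in dataset],
            "jmax": [s.jmax for s in dataset],
        }).to_csv(traits_path, index=False)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def savitzky_golay_smooth(reflectance: np.ndarray, window: int = 21, order: int = 2) -> np.ndarray:
    """Sliding least-squares polynomial smoother.

    Edges are handled by evaluating the polynomial fitted to the first/last
    full window at the edge positions (scipy's 'interp' mode), i.e. no
    padding is ever invented.
    """
    reflectance = np.asarray(reflectance, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    if reflectance.shape[-1] < window:
        raise ValueError("window larger than the spectrum")
    return savgol_filter(reflectance, window_length=window, polyorder=order,
                         axis=-1, mode="interp")


def power_compress(reflectance: np.ndarray, beta: float) -> np.ndarray:
    """Elementwise |X|**beta; beta=1 leaves the input untouched bit-for-bit."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    reflectance = np.asarray(reflectance, dtype=float)
    if beta == 1.0:
        return reflectance.copy()
    return np.abs(reflectance) ** beta


def resample_spectrum(wavelengths: np.ndarray, reflectance: np.ndarray,
                      n_bands: int) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic-spline resampling onto an equally spaced n_bands grid
    spanning the original wavelength range."""
    if n_bands < 4:
        raise ValueError("n_bands must be >= 4")
    wavelengths = np.asarray(wavelengths, dtype=float)
    reflectance = np.asarray(reflectance, dtype=float)
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectraFormatError("wavelengths must be strictly increasing")
    spline = CubicSpline(wavelengths, reflectance, axis=-1, bc_type="natural")
    new_wl = np.linspace(wavelengths[0], wavelengths[-1], n_bands)
    return new_wl, spline(new_wl)


def preprocess_dataset(dataset: SpectralDataset, config: PreprocessConfig) -> SpectralDataset:
    """SG smoothing, then power compression, then optional resampling —
    in that order, applied identically to every sample."""
    wl = dataset.wavelengths
    out = []
    for s in dataset:
        r = savitzky_golay_smooth(s.reflectance, config.sg_window, config.sg_order)
        r = power_compress(r, config.poc_beta)
        w = wl
        if config.resample_bands is not None:
            w, r = resample_spectrum(wl, r, config.resample_bands)
        out.append(replace(s, wavelengths=w, reflectance=np.clip(r, 0.0, None)))
    return SpectralDataset(samples=out, source=dataset.source)
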