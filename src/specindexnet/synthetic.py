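"""Synthetic leaf-spectrum generator with a planted index→trait link.

Spectra mimic green-leaf VNIR reflectance: absorption troughs near 450 nm
(blue) and 670 nm (red), a green peak near 550 nm, a logistic red edge and a
NIR plateau.  Traits are generated from an add-multiply index of the noisy
reflectance at three planted bands (800, 550, 670 nm), so every downstream
module — regression, band recovery, index-form recovery — has a known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SpectralDataset, SpectralSample

DEFAULT_PLANTED_BANDS = {"R_nir": 800.0, "R_g": 550.0, "R_r": 670.0}


@dataclass
class SyntheticConfig:
    n_bands: int = 204
    wl_min: float = 400.0
    wl_max: float = 1000.0
    chlorophyll_range: tuple = (0.35, 0.95)
    nir_plateau_range: tuple = (0.40, 0.60)
    visible_base: float = 0.16
    blue_trough_center: float = 450.0
    blue_trough_width: float = 30.0
    blue_trough_depth: float = 0.11
    red_trough_center: float = 670.0
    red_trough_width: float = 25.0
    red_trough_depth: float = 0.06
    green_peak_center: float = 550.0
    green_peak_width: float = 35.0
    green_peak_height: float = 0.09
    red_edge_center: float = 715.0
    red_edge_scale: float = 12.0
    noise_sd: float = 0.008            # white, per band
    smooth_noise_sd: float = 0.03      # correlated, ~15 nm length scale; makes
    smooth_noise_bands: float = 3.0    # distant same-latent bands poor proxies
    planted_bands: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_BANDS))
    link_a0: float = 35.0
    link_a1: float = 4.0
    trait_noise_sd: float = 2.0
    vcmax_range: tuple = (5.0, 195.0)
    jmax_ratio: float = 1.93
    jmax_sd: float = 14.0
    jmax_range: tuple = (5.0, 350.0)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)


def _gaussian_kernel(sigma: float) -> np.ndarray:
    half = int(np.ceil(3 * sigma))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def generate_leaf_spectrum(config: SyntheticConfig, rng: np.random.Generator) -> SpectralSample:
    """Draw one unlabeled leaf-like spectrum."""
    wl = config.grid
    chl = rng.uniform(*config.chlorophyll_range)
    nir = rng.uniform(*config.nir_plateau_range)

    red_edge = 1.0 / (1.0 + np.exp(-(wl - config.red_edge_center) / config.red_edge_scale))
    base = config.visible_base + (nir - config.visible_base) * red_edge
    base = base + config.green_peak_height * (1.1 - 0.6 * chl) * np.exp(
        -0.5 * ((wl - config.green_peak_center) / config.green_peak_width) ** 2)
    # blue trough depth is deliberately constant (not chlorophyll-scaled):
    # it shapes the spectrum without planting trait signal away from the
    # planted bands
    base = base - 0.7 * config.blue_trough_depth * np.exp(
        -0.5 * ((wl - config.blue_trough_center) / config.blue_trough_width) ** 2)
    base = base - chl * config.red_trough_depth * np.exp(
        -0.5 * ((wl - config.red_trough_center) / config.red_trough_width) ** 2)

    if config.smooth_noise_sd > 0:
        kern = _gaussian_kernel(config.smooth_noise_bands)
        white = rng.normal(size=wl.size + kern.size - 1)
        smooth = np.convolve(white, kern, mode="valid")
        # restore unit variance after smoothing, then scale
        smooth = smooth / np.sqrt(np.sum(kern ** 2))
        base = base + config.smooth_noise_sd * smooth
    if config.noise_sd > 0:
        base = base + rng.normal(scale=config.noise_sd, size=wl.size)

    refl = np.clip(base, 0.01, 0.95)
    return SpectralSample("synthetic", wl, refl)


def planted_index(spectrum: SpectralSample, config: SyntheticConfig) -> float:
    """The planted add-multiply link: (R_nir + R_g) / (R_nir × R_r)."""
    wl = spectrum.wavelengths
    r = spectrum.reflectance

    def at(target):
        return r[int(np.argmin(np.abs(wl - target)))]

    r_nir = at(config.planted_bands["R_nir"])
    r_g = at(config.planted_bands["R_g"])
    r_r = at(config.planted_bands["R_r"])
    return (r_nir + r_g) / (r_nir * r_r)


def assign_traits(spectrum: SpectralSample, config: SyntheticConfig,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Map the planted index affinely to V_cmax; J_max follows at ratio 1.93."""
    idx = planted_index(spectrum, config)
    vcmax = config.link_a0 + config.link_a1 * idx
    if config.trait_noise_sd > 0:
        vcmax += rng.normal(scale=config.trait_noise_sd)
    vcmax = float(np.clip(vcmax, *config.vcmax_range))
    jmax = config.jmax_ratio * vcmax
    if config.jmax_sd > 0:
        jmax += rng.normal(scale=config.jmax_sd)
    jmax = float(np.clip(jmax, *config.jmax_range))
    return vcmax, jmax


def generate_dataset(n: int, config: SyntheticConfig | None = None,
                     seed: int = 0) -> SpectralDataset:
    """n labeled samples, reproducible under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        s = generate_leaf_spectrum(config, rng)
        vcmax, jmax = assign_traits(s, config, rng)
        s.sample_id = f"syn{i:05d}"
        s.vcmax = vcmax
        s.jmax = jmax
        samples.append(s)
    return SpectralDataset(samples=samples, source=f"synthetic(seed={seed})")
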