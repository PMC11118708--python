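"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the statistical structure of the real inputs: smooth
pinwheel-style orientation preference maps, cosine-shaped 8-orientation
pixel tuning with additive Gaussian noise, spatially clustered labeled-cell
sets with a tunable like-to-like orientation bias, model V1 populations,
generatively pooled V2 tuning curves, and texture families paired with
spectrally-matched noise.

All randomness flows through explicit seeded ``numpy.random.Generator``
objects; every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ffmodel, textures
from .oimaps import ORIENTATIONS

__all__ = [
    "MapSimConfig",
    "ConnectivitySimConfig",
    "GroundTruth",
    "OrientationMapSet",
    "CellSet",
    "cosine_tuning",
    "injection_site_po",
    "simulate_orientation_map",
    "simulate_labeled_cells",
    "simulate_texture_family",
    "simulate_v1_population",
    "simulate_v2_pixel",
    "like_to_like_weights",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

RESPONSE_BASELINE = 50.0
RESPONSE_AMPLITUDE = 50.0


@dataclass(frozen=True)
class MapSimConfig:
    height: int = 128
    width: int = 128
    pixels_per_mm: float = 55.0
    map_smoothness: float = 0.75   # mm, hypercolumn-scale correlation length
    noise_sd: float = 0.0          # response units on single-condition maps
    n_orientations: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_orientations != 8:
            raise ValueError("the pipeline is fixed at 8 orientations")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("map dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class ConnectivitySimConfig:
    n_cells: int = 500
    like_to_like_fwhm: float = 22.5   # degrees, axial
    bias_strength: float = 0.5        # 0 = uniform POs, 1 = fully biased
    cluster_scale: float = 8.0        # px, SD of within-cluster scatter
    injection_center: tuple[float, float] = (64.0, 64.0)  # (x, y) px
    injection_radius: float = 6.0     # px
    n_clusters: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must lie in [0, 1]")


@dataclass
class GroundTruth:
    true_po_map: np.ndarray | None = None      # degrees per pixel, [0, 180)
    true_cell_po: np.ndarray | None = None     # degrees per cell
    true_cell_pos: np.ndarray | None = None    # visual-field degrees per cell
    true_weights: np.ndarray | None = None     # generative pooling weights
    injection_po: float | None = None


@dataclass
class OrientationMapSet:
    """Eight single-condition response maps plus the generating config."""

    maps: np.ndarray  # (8, height, width), response units
    config: MapSimConfig = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


def _smooth_axial_field(height: int, width: int, f0_cycles_per_px: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth axial orientation field via the doubled-angle construction:
    band-pass filtered complex white noise, PO = half the argument."""
    z = rng.standard_normal((height, width)) + 1j * rng.standard_normal((height, width))
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    r = np.hypot(fy, fx)
    sigma_f = f0_cycles_per_px / 3.0
    if sigma_f <= 0 or f0_cycles_per_px * max(height, width) < 0.5:
        filt = (r == 0).astype(float)  # constant-field limit
    else:
        filt = np.exp(-((r - f0_cycles_per_px) ** 2) / (2.0 * sigma_f ** 2))
    zf = np.fft.ifft2(np.fft.fft2(z) * filt)
    if np.all(zf == 0):
        zf = np.ones_like(zf)
    return np.mod(np.rad2deg(np.angle(zf)) / 2.0, 180.0)


def cosine_tuning(po_deg: np.ndarray, baseline: float = RESPONSE_BASELINE,
                  amplitude: float = RESPONSE_AMPLITUDE) -> np.ndarray:
    """Raised-cosine (doubled-angle) 8-orientation responses for given POs.

    Returns an array with a leading orientation axis of length 8.
    """
    po = np.asarray(po_deg, dtype=float)
    th = ORIENTATIONS.reshape((8,) + (1,) * po.ndim)
    return baseline + amplitude * np.cos(2.0 * np.deg2rad(th - po))


def simulate_orientation_map(config: MapSimConfig) -> tuple[OrientationMapSet, GroundTruth]:
    """Simulate eight single-condition maps from a smooth pinwheel-style
    orientation field; pixel response to orientation theta is
    ``r0 + a*cos(2*(theta - PO)) + noise``."""
    rng = np.random.default_rng(config.seed)
    wavelength_px = config.map_smoothness * config.pixels_per_mm
    f0 = 1.0 / wavelength_px if wavelength_px > 0 else 0.0
    po = _smooth_axial_field(config.height, config.width, f0, rng)
    maps = cosine_tuning(po)
    if config.noise_sd > 0:
        maps = maps + rng.normal(0.0, config.noise_sd, size=maps.shape)
    return (OrientationMapSet(maps=maps, config=config),
            GroundTruth(true_po_map=po))


@dataclass
class CellSet:
    """Labeled V1 cells: coordinates, POs and provenance."""

    table: pd.DataFrame  # columns x_px, y_px, po_deg, injection_id
    injection_po: float

    @property
    def n_cells(self) -> int:
        return len(self.table)


def _wrapped_normal(center: float, sigma: float, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    return np.mod(rng.normal(center, sigma, size=size), 180.0)


def injection_site_po(true_po_map: np.ndarray, center: tuple[float, float],
                      radius: float) -> float:
    """Doubled-angle circular mean PO over the injection disc."""
    h, w = true_po_map.shape
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2
    z = np.mean(np.exp(2j * np.deg2rad(true_po_map[disc])))
    return float(np.mod(np.rad2deg(np.angle(z)) / 2.0, 180.0))


def simulate_labeled_cells(config: ConnectivitySimConfig,
                           true_po_map: np.ndarray,
                           injection_id: str = "inj0") -> tuple[CellSet, GroundTruth]:
    """Place cells in spatial clusters and draw their POs from a mixture:
    with probability ``bias_strength`` a wrapped Gaussian (given FWHM)
    around the injection-site PO, otherwise uniform on [0, 180)."""
    h, w = true_po_map.shape
    cx, cy = config.injection_center
    if not (config.injection_radius <= cx <= w - 1 - config.injection_radius
            and config.injection_radius <= cy <= h - 1 - config.injection_radius):
        raise ValueError("injection disc extends outside the map bounds")
    rng = np.random.default_rng(config.seed)
    inj_po = injection_site_po(true_po_map, config.injection_center,
                               config.injection_radius)

    centers = np.stack([rng.uniform(0, w - 1, config.n_clusters),
                        rng.uniform(0, h - 1, config.n_clusters)], axis=1)
    which = rng.integers(0, config.n_clusters, size=config.n_cells)
    xy = centers[which] + rng.normal(0.0, config.cluster_scale,
                                     size=(config.n_cells, 2))
    xy[:, 0] = np.clip(xy[:, 0], 0, w - 1)
    xy[:, 1] = np.clip(xy[:, 1], 0, h - 1)

    sigma = config.like_to_like_fwhm / FWHM_TO_SIGMA
    biased = rng.random(config.n_cells) < config.bias_strength
    po = rng.uniform(0.0, 180.0, size=config.n_cells)
    if sigma <= 0:
        po[biased] = inj_po
    else:
        po[biased] = _wrapped_normal(inj_po, sigma, int(biased.sum()), rng)

    table = pd.DataFrame({"x_px": xy[:, 0], "y_px": xy[:, 1], "po_deg": po,
                          "injection_id": injection_id})
    gt = GroundTruth(true_cell_po=po.copy(), injection_po=inj_po)
    return CellSet(table=table, injection_po=inj_po), gt


TEXTURE_KINDS = ("oriented-composite", "thresholded-noise", "plaid")


def _grating_field(size: int, orientation_deg: float, cycles: float,
                   phase: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / size
    th = np.deg2rad(orientation_deg)
    u = yy * np.cos(th) + xx * np.sin(th)
    return np.cos(2 * np.pi * cycles * u + phase)


def _structured_image(kind: str, size: int, rng: np.random.Generator,
                      threshold: float | None = None) -> np.ndarray:
    if kind == "oriented-composite":
        # rectified oriented gratings: rectification aligns phases across
        # harmonics, producing higher-order (edge-like) structure
        img = np.zeros((size, size))
        for _ in range(4):
            g = _grating_field(size, rng.uniform(0, 180),
                               rng.uniform(6, 14), rng.uniform(0, 2 * np.pi))
            img += np.maximum(g, 0.0) ** 2
        return img
    if kind == "thresholded-noise":
        from scipy.ndimage import gaussian_filter
        t = gaussian_filter(rng.standard_normal((size, size)), size / 40.0,
                            mode="wrap")
        t /= t.std()
        thr = -1e30 if threshold is None or np.isneginf(threshold) else threshold
        return np.maximum(t, thr)
    if kind == "plaid":
        ori = rng.uniform(0, 180)
        a = _grating_field(size, ori, rng.uniform(6, 14), rng.uniform(0, 2 * np.pi))
        b = _grating_field(size, ori + 90.0, rng.uniform(6, 14),
                           rng.uniform(0, 2 * np.pi))
        return np.maximum(a, 0.0) * np.maximum(b, 0.0)
    raise ValueError(f"unknown texture kind {kind!r}")


def simulate_texture_family(n_samples: int = 30, kind: str = "oriented-composite",
                            seed: int = 0, size: int = textures.PREPARED_SIZE,
                            threshold: float | None = None) -> textures.TextureFamily:
    """Generate ``n_samples`` structured images plus their spectrally-matched
    noise counterparts, prepared at the standard aperture size."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if kind not in TEXTURE_KINDS:
        raise ValueError(f"unknown texture kind {kind!r}")
    rng = np.random.default_rng(seed)
    texs, noises, raws, raw_noises = [], [], [], []
    for _ in range(n_samples):
        # phase-randomize the raw image, then prepare both: masking first
        # would leak aperture-rim energy into the noise counterpart only
        raw = _structured_image(kind, size, rng, threshold=threshold)
        raw_noise = textures.spectral_noise(raw, rng=rng)
        raws.append(raw)
        raw_noises.append(raw_noise)
        texs.append(textures.prepare_image(raw, size=size))
        noises.append(textures.prepare_image(raw_noise, size=size))
    return textures.TextureFamily(textures=texs, noises=noises,
                                  family_id=f"{kind}-{seed}",
                                  raw_textures=raws, raw_noises=raw_noises)


def simulate_v1_population(n_cells: int, seed: int = 0,
                           po_mode: str = "grid",
                           center_spread_deg: float = 0.5,
                           gamma_range: tuple[float, float] = (1.0, 1.0),
                           sigma_x: float = 0.6, sf: float = 1.0,
                           compute_tunings: bool = True,
                           ) -> tuple[list[ffmodel.V1Cell], np.ndarray | None]:
    """Build a model V1 population of complex cells.

    ``po_mode='grid'`` spaces the preferred orientations evenly over
    [0, 180) (isotropic population); ``'random'`` draws them uniformly.
    Returns the cells and, unless disabled, their phase-averaged
    8-orientation grating tunings (n_cells, 8).
    """
    rng = np.random.default_rng(seed)
    if po_mode == "grid":
        pos = np.arange(n_cells) * (180.0 / n_cells)
    elif po_mode == "random":
        pos = rng.uniform(0.0, 180.0, size=n_cells)
    else:
        raise ValueError("po_mode must be 'grid' or 'random'")
    centers = rng.uniform(-center_spread_deg, center_spread_deg, size=(n_cells, 2))
    gammas = rng.uniform(gamma_range[0], gamma_range[1], size=n_cells)
    cells = [ffmodel.V1Cell(ffmodel.GaborParams(
        xc=float(cx), yc=float(cy), theta_c=float(po), gamma_c=float(g),
        sigma_x=sigma_x, sf=sf)) for (cx, cy), po, g in zip(centers, pos, gammas)]
    tunings = None
    if compute_tunings:
        tunings = np.stack([ffmodel.grating_tuning(c) for c in cells])
    return cells, tunings


def like_to_like_weights(cell_pos_deg: np.ndarray, target_po: float) -> np.ndarray:
    """Generative like-to-like weight profile: cos(2 * (PO - target))."""
    return np.cos(2.0 * np.deg2rad(np.asarray(cell_pos_deg, dtype=float) - target_po))


def simulate_v2_pixel(v1_tunings: np.ndarray, weights: np.ndarray,
                      noise_sd: float = 0.0,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Generate a V2 pixel tuning curve as a known weighted sum of V1
    grating tunings plus additive Gaussian noise."""
    t = np.atleast_2d(np.asarray(v1_tunings, dtype=float))
    w = np.asarray(weights, dtype=float)
    if len(w) != t.shape[0]:
        raise ValueError("one weight per V1 cell required")
    tuning = w @ t
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if rng is None else rng
        tuning = tuning + rng.normal(0.0, noise_sd, size=tuning.shape)
    return tuning, GroundTruth(true_weights=w.copy())
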