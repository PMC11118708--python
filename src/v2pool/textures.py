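"""Texture-vs-noise modulation analysis for model V1 and V2 cells.

A texture family holds structured grayscale images and their
spectrally-matched noise counterparts (identical Fourier amplitude spectra,
randomized phases).  Prepared images are 320x320 px inside a circular
aperture of diameter 320, at 100 px per degree of visual field.  Each image
is presented at 8 rotations in 22.5-deg steps; the modulation index of a
cell is computed at the rotation with the most reliable differential
response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.transform import resize, rotate

from . import ffmodel

__all__ = [
    "TextureFamily",
    "MIResult",
    "PREPARED_SIZE",
    "PX_PER_DEG",
    "ROTATIONS",
    "spectral_noise",
    "prepare_image",
    "rotate_family",
    "standardize",
    "image_raster",
    "cell_response_to_image",
    "family_responses",
    "modulation_index",
    "compare_populations",
]

PREPARED_SIZE = 320
PX_PER_DEG = 100.0
ROTATIONS = np.arange(8) * 22.5


def _circular_mask(size: int = PREPARED_SIZE) -> np.ndarray:
    r = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - r) ** 2 + (xx - r) ** 2 <= (size / 2.0) ** 2


def image_raster(size: int = PREPARED_SIZE,
                 px_per_deg: float = PX_PER_DEG,
                 center: tuple[float, float] = (0.0, 0.0)) -> "ffmodel.Raster":
    """Raster aligned pixel-for-pixel with a prepared ``size``-px image,
    centred on ``center`` (degrees) at the standard px/deg scale."""
    step = 1.0 / px_per_deg
    ax = (np.arange(size) - (size - 1) / 2.0) * step
    x, y = np.meshgrid(center[0] + ax, center[1] + ax)
    return ffmodel.Raster(x=x, y=y, step=step)


def spectral_noise(image: np.ndarray,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> np.ndarray:
    """Phase-randomize an image while preserving its amplitude spectrum.

    Random phases are taken from the Fourier transform of a real white-noise
    field, which guarantees Hermitian symmetry (real output); the DC phase
    is kept from the original so mean luminance is untouched.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("spectral_noise requires a 2-D grayscale image")
    rng = np.random.default_rng(seed) if rng is None else rng
    F = np.fft.fft2(img)
    phi = np.angle(np.fft.fft2(rng.standard_normal(img.shape)))
    phi[0, 0] = np.angle(F[0, 0])
    return np.real(np.fft.ifft2(np.abs(F) * np.exp(1j * phi)))


def prepare_image(image: np.ndarray, size: int = PREPARED_SIZE) -> np.ndarray:
    """Center-crop to a square, resize to ``size`` and apply the circular
    aperture (outside filled with the image mean)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("need a 2-D image of usable size")
    h, w = img.shape
    s = min(h, w)
    r0 = (h - s) // 2
    c0 = (w - s) // 2
    img = img[r0:r0 + s, c0:c0 + s]
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, mode="reflect",
                     anti_aliasing=img.shape[0] > size)
    mask = _circular_mask(size)
    fill = float(img[mask].mean())  # mean luminance inside the aperture
    out = np.full((size, size), fill)
    out[mask] = img[mask]
    return out


@dataclass
class TextureFamily:
    """Paired structured / spectrally-matched-noise images.

    ``textures``/``noises`` are prepared (cropped, resized, masked); the
    optional raw pairs predate preparation and have exactly matching
    amplitude spectra (the aperture changes each prepared image's spectrum
    slightly, and differently).
    """

    textures: list[np.ndarray]
    noises: list[np.ndarray]
    family_id: str = "family"
    rotations: np.ndarray = field(default_factory=lambda: ROTATIONS.copy())
    raw_textures: list[np.ndarray] | None = None
    raw_noises: list[np.ndarray] | None = None

    def __post_init__(self):
        if len(self.textures) != len(self.noises):
            raise ValueError("texture/noise pairing must be 1:1")

    @property
    def n_pairs(self) -> int:
        return len(self.textures)

    def sample_counts(self) -> tuple[int, int]:
        """(texture, noise) sample counts after rotation augmentation."""
        n = self.n_pairs * len(self.rotations)
        return n, n


def rotate_family(family: TextureFamily) -> dict[str, np.ndarray]:
    """Rotate every prepared image about the aperture center at each family
    rotation, re-applying the mask.

    Returns arrays of shape (n_rotations, n_pairs, size, size) under keys
    ``"textures"`` and ``"noises"``.
    """
    mask = _circular_mask(family.textures[0].shape[0])
    out = {}
    for key, imgs in (("textures", family.textures), ("noises", family.noises)):
        size = imgs[0].shape[0]
        arr = np.empty((len(family.rotations), len(imgs), size, size))
        for i, img in enumerate(imgs):
            if img.shape != (size, size):
                raise ValueError("images must be prepared (uniform square size)")
            fill = float(img[mask].mean())
            for k, ang in enumerate(family.rotations):
                if ang == 0:
                    rot = img.copy()
                else:
                    rot = rotate(img, ang, resize=False, order=1,
                                 mode="constant", cval=fill)
                rot[~mask] = fill
                arr[k, i] = rot
        out[key] = arr
    return out


def standardize(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean, unit-SD standardization over the aperture.

    A zero-variance image raises ``ValueError`` (callers flag it)."""
    img = np.asarray(image, dtype=float)
    mask = _circular_mask(img.shape[0]) if mask is None else mask
    mu = img[mask].mean()
    sd = img[mask].std()
    if sd == 0:
        raise ValueError("zero-variance image")
    out = (img - mu) / sd
    out[~mask] = 0.0
    return out


def cell_response_to_image(cell: ffmodel.V1Cell, image: np.ndarray,
                           raster: ffmodel.Raster) -> float:
    """Complex-cell response to a standardized image on a shared raster.

    The RF filters are already standardized in practice (zero-mean up to
    envelope truncation, unit norm); the image is standardized over the
    aperture before the dot product, making the response invariant to affine
    luminance changes.  Constant images yield response 0.
    """
    try:
        std = standardize(image)
    except ValueError:
        return 0.0
    return ffmodel.complex_response(cell, std, raster)


def family_responses(cells: list[ffmodel.V1Cell], weights: np.ndarray,
                     rotated: dict[str, np.ndarray], raster: ffmodel.Raster,
                     ) -> dict[str, np.ndarray]:
    """Responses of the V1 population and the pooled V2 unit to every
    rotated sample.

    ``weights`` is (n_cells,) for a single V2 unit.  Returns ``"v1"`` with
    shape (n_cells, n_rotations, n_pairs, 2) — last axis texture/noise —
    and ``"v2"`` with shape (n_rotations, n_pairs, 2).
    """
    n_rot, n_pairs = rotated["textures"].shape[:2]
    # stack all quadrature filters once: (n_cells * 4, n_px)
    filt_rows = []
    for cell in cells:
        if cell.mode != "complex":
            raise ValueError("family_responses expects complex-mode cells")
        filt_rows.extend(f.ravel() for f in cell.filters(raster))
    F = np.stack(filt_rows)
    v1 = np.zeros((len(cells), n_rot, n_pairs, 2))
    for k in range(n_rot):
        for i in range(n_pairs):
            for c, img in enumerate((rotated["textures"][k, i],
                                     rotated["noises"][k, i])):
                try:
                    std = standardize(img)
                except ValueError:
                    continue
                proj = np.maximum(F @ std.ravel(), 0.0)
                v1[:, k, i, c] = proj.reshape(len(cells), 4).sum(axis=1)
    v2 = np.tensordot(np.asarray(weights, dtype=float), v1, axes=(0, 0))
    return {"v1": v1, "v2": v2}


@dataclass
class MIResult:
    """Modulation index of one cell for one texture family."""

    mi: float                 # at the selected rotation
    selected_rotation: int    # index into the family rotations
    rotation_score: np.ndarray  # mean(d)/var(d) per rotation
    mi_per_rotation: np.ndarray
    mean_texture: float       # R_T at the selected rotation
    mean_noise: float         # R_N at the selected rotation
    mi_per_pair: np.ndarray   # (n_pairs,) at the selected rotation
    negative_response_flag: bool = False


def modulation_index(texture_responses: np.ndarray,
                     noise_responses: np.ndarray) -> MIResult:
    """Compute the texture modulation index of one cell.

    Inputs are (n_rotations, n_pairs) response arrays.  Per rotation the
    differential response d = R_T - R_N over pairs is scored by
    mean(d)/var(d); the rotation with the largest score is selected and
    MI = (mean R_T - mean R_N) / (mean R_T + mean R_N) computed there.
    A negative mean response is flagged (MI still reported, not clipped).
    """
    rt = np.asarray(texture_responses, dtype=float)
    rn = np.asarray(noise_responses, dtype=float)
    if rt.shape != rn.shape or rt.ndim != 2:
        raise ValueError("paired (n_rotations, n_pairs) responses required")
    d = rt - rn
    var = d.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(var > 0, d.mean(axis=1) / var,
                         np.sign(d.mean(axis=1)) * np.inf)
    score = np.where(np.isnan(score), 0.0, score)
    k = int(np.argmax(score))
    mt = rt.mean(axis=1)
    mn = rn.mean(axis=1)
    tot = mt + mn
    with np.errstate(divide="ignore", invalid="ignore"):
        mi_rot = np.where(tot != 0, (mt - mn) / tot, np.nan)
    if tot[k] == 0:
        raise ValueError("undefined MI: mean texture + noise response is 0 "
                         "at the selected rotation")
    pair_tot = rt[k] + rn[k]
    with np.errstate(divide="ignore", invalid="ignore"):
        mi_pair = np.where(pair_tot != 0, (rt[k] - rn[k]) / pair_tot, np.nan)
    return MIResult(mi=float(mi_rot[k]), selected_rotation=k,
                    rotation_score=score, mi_per_rotation=mi_rot,
                    mean_texture=float(mt[k]), mean_noise=float(mn[k]),
                    mi_per_pair=mi_pair,
                    negative_response_flag=bool(mt[k] < 0 or mn[k] < 0))


@dataclass
class PopulationComparison:
    t: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def compare_populations(mis_a, mis_b) -> PopulationComparison:
    """Two-sample t-test between per-cell MI values of two populations."""
    a = np.asarray(mis_a, dtype=float)
    b = np.asarray(mis_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std() == 0 and b.std() == 0:
        t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    else:
        res = sps.ttest_ind(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    return PopulationComparison(t=t, p=p, mean_a=float(a.mean()),
                                mean_b=float(b.mean()), sd_a=float(a.std(ddof=1)),
                                sd_b=float(b.std(ddof=1)))
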