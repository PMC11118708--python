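"""Optical-imaging map processing: single-condition response maps, per-pixel
tuning curves, Von Mises fits and vector-sum preferred-orientation maps.

Frame indices in the docstrings are 1-based ("first two frames", "frames 15
to 20"), matching imaging-lab convention; array code uses the corresponding
0-based slices.  All orientations are axial degrees in ``[0, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

__all__ = [
    "ORIENTATIONS",
    "ResponseStack",
    "POMap",
    "VonMisesFit",
    "single_condition_maps",
    "vector_sum_po",
    "vector_sum_po_single",
    "fit_von_mises",
    "von_mises",
    "hwhh_from_kappa",
]

#: the eight grating orientations, degrees
ORIENTATIONS = np.arange(8) * 22.5

HIGHPASS_SIGMA_NARROW = 2.5   # px, response smoothing
HIGHPASS_SIGMA_WIDE = 25.0    # px, low-frequency noise estimate (~0.45 mm)
CLIP_LIMIT = 100.0


@dataclass
class ResponseStack:
    """Raw trial-resolved imaging data.

    ``data`` has shape (n_trials, n_frames, rows, cols); ``orientation``
    gives the grating orientation of each trial in degrees.
    """

    data: np.ndarray
    orientation: np.ndarray
    frame_rate: float = 5.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("stack must be (trial, frame, row, col)")
        if self.data.shape[1] < 20:
            raise ValueError("need >= 20 frames per trial for frame-window extraction")
        if len(self.orientation) != self.data.shape[0]:
            raise ValueError("one orientation label per trial required")


@dataclass
class POMap:
    """Per-pixel preferred orientation and vector-sum magnitude."""

    po: np.ndarray          # degrees, axial
    magnitude: np.ndarray   # resultant length / total response, in [0, 1]
    vessel_mask: np.ndarray  # True where blood vessel (excluded)
    undefined: np.ndarray    # True where total response is 0 (PO meaningless)


def _highpass(img: np.ndarray) -> np.ndarray:
    """Band-pass: lightly smoothed map minus heavily smoothed map."""
    return (gaussian_filter(img, HIGHPASS_SIGMA_NARROW, mode="reflect")
            - gaussian_filter(img, HIGHPASS_SIGMA_WIDE, mode="reflect"))


def single_condition_maps(stack: ResponseStack,
                          vessel_mask: np.ndarray | None = None,
                          control_image: np.ndarray | None = None) -> np.ndarray:
    """Reduce a trial stack to eight rescaled single-condition maps.

    Per trial: (mean of frames 15-20) - (mean of frames 1-2), inverted,
    clipped to +/-100, divided by the control image (by default the average
    of the first five frames of the first recorded trial), band-pass
    filtered; trials are then averaged per orientation excluding the first
    recorded trial; the pixelwise minimum across orientations is subtracted
    and the set rescaled so non-vessel values span [0, 100].

    Returns an (8, rows, cols) array ordered by ``ORIENTATIONS``.
    """
    data = stack.data
    n_trials = data.shape[0]
    shape = data.shape[2:]
    if vessel_mask is None:
        vessel_mask = np.zeros(shape, dtype=bool)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.all():
        raise ValueError("vessel mask covers the entire image")
    if control_image is None:
        control_image = data[0, :5].mean(axis=0)
    control_image = np.asarray(control_image, dtype=float)
    if np.any(control_image == 0):
        raise ValueError("control image contains zeros")

    resp = data[:, 14:20].mean(axis=1) - data[:, 0:2].mean(axis=1)
    resp *= -1.0
    np.clip(resp, -CLIP_LIMIT, CLIP_LIMIT, out=resp)
    resp /= control_image
    for t in range(n_trials):
        resp[t] = _highpass(resp[t])

    maps = np.zeros((len(ORIENTATIONS),) + shape)
    for k, ori in enumerate(ORIENTATIONS):
        sel = np.isclose(stack.orientation, ori)
        sel[0] = False  # the first recorded trial is excluded (control trial)
        if not sel.any():
            raise ValueError(f"no usable trials for orientation {ori}")
        maps[k] = resp[sel].mean(axis=0)

    maps -= maps.min(axis=0)  # stimulus non-specific response
    return rescale_condition_maps(maps, vessel_mask)


def rescale_condition_maps(maps: np.ndarray, vessel_mask: np.ndarray) -> np.ndarray:
    """Rescale a condition-map set so non-vessel values span [0, 100].

    Divides by the maximum (over non-vessel pixels) of the across-orientation
    max-minus-min map and multiplies by 100.  Idempotent; an all-zero set is
    returned unchanged.
    """
    diff = maps.max(axis=0) - maps.min(axis=0)
    scale = diff[~vessel_mask].max() if (~vessel_mask).any() else 0.0
    if scale == 0:
        return maps.copy()
    return maps / scale * 100.0


def vector_sum_po(maps: np.ndarray, vessel_mask: np.ndarray | None = None) -> POMap:
    """Pixel-by-pixel vector summation of eight single-condition maps.

    The resultant of ``sum_k r_k * exp(i * 2 * theta_k)`` gives the PO as
    half its argument; magnitude is the resultant length normalized by the
    summed response (0, and flagged undefined, where the sum is 0).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != len(ORIENTATIONS):
        raise ValueError("expected 8 single-condition maps")
    if vessel_mask is None:
        vessel_mask = np.zeros(maps.shape[1:], dtype=bool)
    phase = np.exp(2j * np.deg2rad(ORIENTATIONS))
    resultant = np.tensordot(phase, maps, axes=(0, 0))
    total = maps.sum(axis=0)
    mag = np.zeros_like(total)
    nz = total != 0
    mag[nz] = np.abs(resultant[nz]) / total[nz]
    undefined = np.abs(resultant) <= 1e-12 * np.maximum(np.abs(total), 1.0)
    po = np.mod(np.rad2deg(np.angle(resultant)) / 2.0, 180.0)
    po[undefined] = 0.0
    return POMap(po=po, magnitude=mag, vessel_mask=np.asarray(vessel_mask, bool),
                 undefined=undefined)


def vector_sum_po_single(responses: np.ndarray) -> float:
    """Vector-sum PO (degrees) of one 8-point tuning curve."""
    r = np.asarray(responses, dtype=float)
    res = np.sum(r * np.exp(2j * np.deg2rad(ORIENTATIONS)))
    return float(np.mod(np.rad2deg(np.angle(res)) / 2.0, 180.0))


def von_mises(theta_deg: np.ndarray, baseline: float, amplitude: float,
              mu_deg: float, kappa: float) -> np.ndarray:
    """Axial Von Mises tuning: ``b + a * exp(kappa * cos(2*(theta - mu)))``."""
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - mu_deg)
    return baseline + amplitude * np.exp(kappa * np.cos(2.0 * d))


def hwhh_from_kappa(kappa: float) -> float:
    """Half width at half height (deg) of the axial Von Mises peak.

    Half height is measured from the baseline: solves
    ``exp(kappa*cos(2h)) = exp(kappa)/2``; flat curves (no solution) return
    the maximal 90 deg.
    """
    if kappa <= 0:
        return 90.0
    c = 1.0 - np.log(2.0) / kappa
    if c < -1.0:
        return 90.0
    return float(np.rad2deg(np.arccos(c)) / 2.0)


@dataclass
class VonMisesFit:
    baseline: float
    amplitude: float
    mu: float       # degrees, axial
    kappa: float
    hwhh: float     # degrees
    rss: float
    flagged: bool = False


def fit_von_mises(tc: np.ndarray, orientations: np.ndarray = ORIENTATIONS) -> VonMisesFit:
    """Levenberg-Marquardt fit of the axial Von Mises to an 8-point curve.

    mu is initialized at the vector-sum PO with restarts at +/-22.5 and
    +/-45 deg offsets to escape local minima.  A flat curve or a failed fit
    is flagged rather than raised.
    """
    r = np.asarray(tc, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("tuning curve must be finite")
    if np.ptp(r) == 0:
        return VonMisesFit(float(r[0]), 0.0, 0.0, 0.0, 90.0, 0.0, flagged=True)

    po0 = vector_sum_po_single(r)
    k0 = 1.0
    a0 = np.ptp(r) / (np.exp(k0) - np.exp(-k0))
    b0 = r.min() - a0 * np.exp(-k0)

    def resid(p):
        return von_mises(orientations, p[0], p[1], p[2], p[3]) - r

    best = None
    for dmu in (0.0, 22.5, -22.5, 45.0, -45.0):
        try:
            sol = least_squares(resid, [b0, a0, po0 + dmu, k0], method="lm",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= (1e-8 * np.ptp(r)) ** 2:  # already a near-perfect fit
            break
    if best is None:
        return VonMisesFit(float(r.mean()), 0.0, po0, 0.0, 90.0,
                           float(np.sum((r - r.mean()) ** 2)), flagged=True)

    b, a, mu, k = best.x
    if k < 0:  # exp(k*cos) with k<0 is the same curve with mu shifted 90 deg
        k = -k
        mu += 90.0
    mu = float(np.mod(mu, 180.0))
    rss = float(2 * best.cost)
    flagged = (a <= 0) or not best.success
    return VonMisesFit(float(b), float(a), mu, float(k), hwhh_from_kappa(float(k)),
                       rss, flagged=flagged)
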