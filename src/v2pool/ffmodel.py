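"""Linear feedforward pooling model: Gabor V1 units, tuning-similarity
weights, V2 responses as weighted sums, receptive-field rendering and
eight-fold leave-one-out validation.

Conventions
-----------
Orientations are axial, in degrees on ``[0, 180)``; the eight grating
orientations are ``0, 22.5, ..., 157.5``.  Visual-field coordinates are in
degrees, rasters are square pixel lattices with a fixed step (default
0.01 deg/px).  A grating of orientation ``theta`` has its carrier varying
along the axis rotated by ``theta`` from vertical, matching the filter
parameterization, so a filter with ``theta_c == theta`` is optimally driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .oimaps import ORIENTATIONS, fit_von_mises, vector_sum_po_single

__all__ = [
    "GaborParams",
    "Raster",
    "V1Cell",
    "WeightMatrix",
    "CVResult",
    "make_raster",
    "gabor_filter",
    "grating_image",
    "simple_response",
    "complex_response",
    "grating_tuning",
    "estimate_aspect_ratio",
    "compute_weights",
    "v2_response",
    "render_v2_rf",
    "loo_cross_validate",
    "ASPECT_RATIO_BANK",
]

#: candidate aspect ratios evaluated when fitting a measured tuning curve
ASPECT_RATIO_BANK = np.linspace(0.1, 4.0, 40)

COMPLEX_PHASES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


@dataclass(frozen=True)
class GaborParams:
    """Parameters of an oriented Gabor receptive field.

    ``sigma_x`` is the envelope standard deviation along the axis
    orthogonal to the carrier; the envelope SD along the carrier axis is
    ``sigma_x / gamma_c``.  The returned filters are L2-normalized, so no
    explicit amplitude is stored.
    """

    xc: float = 0.0
    yc: float = 0.0
    theta_c: float = 0.0
    gamma_c: float = 1.0
    sigma_x: float = 0.6
    sf: float = 1.0
    phi: float = 0.0

    def envelope_halfwidth(self, n_sigma: float = 3.0) -> float:
        """Half-extent (deg) covering the envelope to ``n_sigma`` SDs."""
        return n_sigma * self.sigma_x * max(1.0, 1.0 / max(self.gamma_c, 1e-6))


@dataclass(frozen=True)
class Raster:
    """Square evaluation lattice in visual-field degrees."""

    x: np.ndarray
    y: np.ndarray
    step: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def matches(self, other: "Raster") -> bool:
        return self.x.shape == other.x.shape and np.allclose(self.x, other.x) and np.allclose(self.y, other.y)


def make_raster(center: tuple[float, float] = (0.0, 0.0), half_width: float = 2.0,
                step: float = 0.01) -> Raster:
    """Build a square raster centred on ``center`` spanning ``±half_width``."""
    if step <= 0 or half_width <= 0:
        raise ValueError("step and half_width must be positive")
    n = int(round(2 * half_width / step)) + 1
    ax = np.linspace(-half_width, half_width, n)
    x, y = np.meshgrid(center[0] + ax, center[1] + ax)
    return Raster(x=x, y=y, step=step)


def _rotated_coords(params: GaborParams, raster: Raster):
    dx = raster.x - params.xc
    dy = raster.y - params.yc
    th = np.deg2rad(params.theta_c)
    xp = -dy * np.sin(th) + dx * np.cos(th)
    yp = dy * np.cos(th) + dx * np.sin(th)
    return xp, yp


def gabor_filter(params: GaborParams, raster: Raster) -> np.ndarray:
    """Evaluate the Gabor on ``raster`` and normalize to unit L2 norm.

    Raises ``ValueError`` when the raster undersamples the carrier
    (fewer than 4 samples per cycle).
    """
    if raster.step > 1.0 / (4.0 * params.sf):
        raise ValueError(
            f"raster step {raster.step} too coarse for carrier sf={params.sf} "
            "(need >= 4 samples per cycle)")
    xp, yp = _rotated_coords(params, raster)
    env = np.exp(-(xp ** 2 + params.gamma_c ** 2 * yp ** 2) / (2.0 * params.sigma_x ** 2))
    g = env * np.cos(2 * np.pi * params.sf * yp + params.phi)
    nrm = np.linalg.norm(g)
    if nrm == 0:
        raise ValueError("degenerate Gabor: zero norm on this raster")
    return g / nrm


def grating_image(raster: Raster, orientation: float, sf: float = 1.0,
                  phase: float = 0.0, contrast: float = 1.0) -> np.ndarray:
    """Full-field sinusoidal grating of the given axial orientation."""
    th = np.deg2rad(orientation)
    yp = raster.y * np.cos(th) + raster.x * np.sin(th)
    return contrast * np.cos(2 * np.pi * sf * yp + phase)


@dataclass
class V1Cell:
    """A model V1 unit: phase-free Gabor parameters plus response mode."""

    params: GaborParams
    mode: str = "complex"  # simple_even | simple_odd | complex
    tuning: np.ndarray | None = None  # measured 8-orientation tuning

    _filters: tuple[np.ndarray, ...] | None = field(default=None, repr=False)
    _filter_raster: Raster | None = field(default=None, repr=False)

    def phases(self) -> tuple[float, ...]:
        if self.mode == "simple_even":
            return (0.0,)
        if self.mode == "simple_odd":
            return (np.pi / 2,)
        if self.mode == "complex":
            return COMPLEX_PHASES
        raise ValueError(f"unknown mode {self.mode!r}")

    def filters(self, raster: Raster) -> tuple[np.ndarray, ...]:
        """Quadrature filter set on ``raster`` (cached per raster)."""
        if self._filters is not None and self._filter_raster is not None \
                and self._filter_raster.matches(raster):
            return self._filters
        if self.mode == "complex":
            # build the pi-offset pair as exact negations so that
            # contrast-inversion invariance holds bit-exactly
            even = gabor_filter(replace(self.params, phi=0.0), raster)
            odd = gabor_filter(replace(self.params, phi=np.pi / 2), raster)
            filts = (even, odd, -even, -odd)
        else:
            filts = tuple(gabor_filter(replace(self.params, phi=p), raster)
                          for p in self.phases())
        self._filters = filts
        self._filter_raster = raster
        return filts


def simple_response(filt: np.ndarray, image: np.ndarray) -> float:
    """Half-wave rectified inner product of filter and image."""
    if filt.shape != image.shape:
        raise ValueError(f"raster mismatch: {filt.shape} vs {image.shape}")
    return max(0.0, float(np.vdot(filt, image).real))


def complex_response(cell: V1Cell, image: np.ndarray, raster: Raster) -> float:
    """Sum of rectified responses of the four quadrature-phase filters."""
    if cell.mode != "complex":
        raise ValueError("complex_response requires a complex-mode cell")
    return sum(simple_response(f, image) for f in cell.filters(raster))


def cell_response(cell: V1Cell, image: np.ndarray, raster: Raster) -> float:
    """Response of a cell in whatever mode it is configured."""
    if cell.mode == "complex":
        return complex_response(cell, image, raster)
    return simple_response(cell.filters(raster)[0], image)


def _local_raster(cell: V1Cell, step: float = 0.01, n_sigma: float = 3.0,
                  margin: float = 0.5) -> Raster:
    """Axis-aligned rectangle covering the rotated envelope to ``n_sigma``
    SDs (plus margin); much smaller than a square window for elongated RFs."""
    p = cell.params
    th = np.deg2rad(p.theta_c)
    sx = p.sigma_x                      # SD along x' (orthogonal to carrier)
    sy = p.sigma_x / max(p.gamma_c, 1e-6)  # SD along y' (carrier axis)
    hx = n_sigma * (sx * abs(np.cos(th)) + sy * abs(np.sin(th))) + margin
    hy = n_sigma * (sx * abs(np.sin(th)) + sy * abs(np.cos(th))) + margin
    nx = int(round(2 * hx / step)) + 1
    ny = int(round(2 * hy / step)) + 1
    ax = np.linspace(-hx, hx, nx) + p.xc
    ay = np.linspace(-hy, hy, ny) + p.yc
    x, y = np.meshgrid(ax, ay)
    return Raster(x=x, y=y, step=step)


def grating_tuning(cell: V1Cell, orientations: np.ndarray = ORIENTATIONS,
                   n_phases: int = 8, sf: float | None = None,
                   raster: Raster | None = None) -> np.ndarray:
    """Phase-averaged grating responses of ``cell`` at each orientation.

    Gratings are evaluated at ``n_phases`` evenly spaced spatial phases and
    the responses averaged, emulating drifting gratings.  When ``raster`` is
    omitted a local window covering the cell's envelope is used; gratings
    are full-field so the restriction is exact up to envelope truncation.
    """
    sf = cell.params.sf if sf is None else sf
    if raster is None:
        # private local window: build filters without caching them on the
        # cell (a cached 4-filter set per cell is ~7 MB; populations of
        # hundreds of cells would hoard gigabytes)
        raster = _local_raster(cell)
        if cell.mode == "complex":
            even = gabor_filter(replace(cell.params, phi=0.0), raster)
            odd = gabor_filter(replace(cell.params, phi=np.pi / 2), raster)
            filts = (even, odd, -even, -odd)
        else:
            filts = tuple(gabor_filter(replace(cell.params, phi=p), raster)
                          for p in cell.phases())
    else:
        filts = cell.filters(raster)
    phases = 2 * np.pi * np.arange(n_phases) / n_phases
    out = np.empty(len(orientations))
    fl = np.stack([f.ravel() for f in filts])
    for k, ori in enumerate(orientations):
        # cos(arg + psi) = cos(arg) cos(psi) - sin(arg) sin(psi): two dot
        # products per filter give the response at every spatial phase
        th = np.deg2rad(ori)
        arg = 2 * np.pi * sf * (raster.y * np.cos(th) + raster.x * np.sin(th))
        cs = np.stack([np.cos(arg).ravel(), np.sin(arg).ravel()], axis=1)
        C, S = (fl @ cs).T  # (n_filters,) each
        proj = C[None, :] * np.cos(phases)[:, None] - S[None, :] * np.sin(phases)[:, None]
        out[k] = np.maximum(proj, 0.0).sum(axis=1).mean()
    return out


_BANK_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _aspect_ratio_bank(sigma_x: float, sf: float, step: float,
                       n_phases: int) -> tuple[np.ndarray, np.ndarray]:
    key = (round(sigma_x, 9), round(sf, 9), round(step, 9), n_phases)
    if key not in _BANK_CACHE:
        tunings = np.empty((len(ASPECT_RATIO_BANK), len(ORIENTATIONS)))
        for i, g in enumerate(ASPECT_RATIO_BANK):
            cell = V1Cell(GaborParams(gamma_c=float(g), sigma_x=sigma_x, sf=sf))
            tunings[i] = grating_tuning(cell, n_phases=n_phases,
                                        raster=_local_raster(cell, step))
        _BANK_CACHE[key] = (ASPECT_RATIO_BANK.copy(), tunings)
    return _BANK_CACHE[key]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def estimate_aspect_ratio(measured: np.ndarray, sigma_x: float = 0.6,
                          sf: float = 1.0, step: float = 0.01,
                          n_phases: int = 8) -> tuple[float, float, bool]:
    """Pick the bank aspect ratio whose simulated complex-cell tuning best
    matches ``measured`` (SSE between unit-normalized, PO-aligned curves).

    Returns ``(gamma_c, sse, flagged)``; flat measured tuning is flagged and
    defaults to gamma 1.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape != (len(ORIENTATIONS),):
        raise ValueError("measured tuning must have 8 entries")
    if np.ptp(measured) <= 1e-12 * max(1.0, abs(measured).max()):
        return 1.0, np.inf, True
    gammas, bank = _aspect_ratio_bank(sigma_x, sf, step, n_phases)
    po = vector_sum_po_single(measured)
    shift = int(round(po / 22.5)) % 8  # bank cells prefer 0 deg
    m = _unit(measured)
    best_g, best_sse = 1.0, np.inf
    for g, tun in zip(gammas, bank):
        sim = _unit(np.roll(tun, shift))
        sse = float(np.sum((sim - m) ** 2))
        if sse < best_sse:
            best_g, best_sse = float(g), sse
    return best_g, best_sse, False


@dataclass
class WeightMatrix:
    """Tuning-similarity weights between V1 cells (rows) and V2 pixels."""

    w: np.ndarray  # (n_cells, n_pixels)
    excluded_cells: list[int]
    excluded_pixels: list[int]


def _centered_unit_rows(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = t - t.mean(axis=1, keepdims=True)
    n = np.linalg.norm(c, axis=1)
    ok = n > 0
    c[ok] /= n[ok, None]
    return c, ok


def compute_weights(v1_tunings: np.ndarray, v2_tunings: np.ndarray) -> WeightMatrix:
    """Weight = cosine similarity of mean-subtracted tuning vectors.

    Constant (zero-variance) tuning curves yield undefined weights; the
    corresponding rows/columns are zeroed and reported as excluded.
    """
    v1 = np.atleast_2d(np.asarray(v1_tunings, dtype=float))
    v2 = np.atleast_2d(np.asarray(v2_tunings, dtype=float))
    if v1.shape[1] != v2.shape[1]:
        raise ValueError("tuning vector lengths differ")
    c1, ok1 = _centered_unit_rows(v1.copy())
    c2, ok2 = _centered_unit_rows(v2.copy())
    w = c1 @ c2.T
    w[~ok1, :] = 0.0
    w[:, ~ok2] = 0.0
    np.clip(w, -1.0, 1.0, out=w)
    return WeightMatrix(w=w,
                        excluded_cells=list(np.flatnonzero(~ok1)),
                        excluded_pixels=list(np.flatnonzero(~ok2)))


def v2_response(weights: np.ndarray, v1_responses: np.ndarray) -> float:
    """Linear pooled response: weighted sum of V1 responses, no rectification."""
    weights = np.asarray(weights, dtype=float)
    v1_responses = np.asarray(v1_responses, dtype=float)
    if weights.shape != v1_responses.shape:
        raise ValueError("weight / response length mismatch")
    return float(weights @ v1_responses)


def render_v2_rf(cells: list[V1Cell], weights: np.ndarray, raster: Raster,
                 parity: str = "even") -> np.ndarray:
    """Weighted spatial sum of the cells' even- or odd-parity Gabors."""
    if parity not in ("even", "odd"):
        raise ValueError("parity must be 'even' or 'odd'")
    phi = 0.0 if parity == "even" else np.pi / 2
    rf = np.zeros(raster.shape)
    for cell, w in zip(cells, weights, strict=True):
        rf += w * gabor_filter(replace(cell.params, phi=phi), raster)
    return rf


@dataclass
class CVResult:
    """Per-pixel outcome of the eight-fold leave-one-out validation.

    Two calibrations of the arbitrary-unit pooled predictions are reported:
    ``relative_error`` calibrates the LOO-assembled 8-point raw prediction to
    the measured curve with one affine (gain + offset) fit per pixel — every
    raw point is still predicted by a model blind to its measurement;
    ``relative_error_trainfit`` instead fits the affine map per fold on the 7
    training orientations only and extrapolates to the held-out one.
    """

    predicted: np.ndarray       # (n_pixels, 8) assembled + affine-calibrated
    predicted_trainfit: np.ndarray  # (n_pixels, 8) per-fold calibrated
    measured: np.ndarray        # (n_pixels, 8)
    relative_error: np.ndarray  # (n_pixels, 8) |pred-meas| / measured range
    relative_error_trainfit: np.ndarray
    po_abs_error: np.ndarray    # (n_pixels,) deg, from LOO-assembled tuning
    hwhh_abs_error: np.ndarray  # (n_pixels,) deg
    po_abs_error_full: np.ndarray  # from the full-data (non-CV) model

    @property
    def mean_relative_error(self) -> float:
        return float(np.nanmean(self.relative_error))


def _affine_calibrate(pred_train, meas_train, pred_test):
    # least-squares gain + offset fitted on the training orientations
    A = np.stack([pred_train, np.ones_like(pred_train)], axis=1)
    coef, *_ = np.linalg.lstsq(A, meas_train, rcond=None)
    return coef[0] * pred_test + coef[1], coef


def _po_hwhh(tuning: np.ndarray) -> tuple[float, float]:
    po = vector_sum_po_single(tuning)
    fit = fit_von_mises(tuning)
    return po, fit.hwhh


def _axial_err(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def loo_cross_validate(v1_tunings: np.ndarray, v2_tunings: np.ndarray,
                       v1_grating_responses: np.ndarray | None = None,
                       v1_cells: list[V1Cell] | None = None) -> CVResult:
    """Eight-fold leave-one-out validation of the pooling model.

    For every fold one orientation is held out; weights are recomputed from
    the remaining 7-point tuning vectors; model V1 responses to the held-out
    grating (phase-averaged Gabor responses — supplied directly or computed
    from ``v1_cells``) drive the pooled prediction, which is affine-calibrated
    on the 7 training orientations before comparison to the measurement.
    """
    v1 = np.atleast_2d(np.asarray(v1_tunings, dtype=float))
    v2 = np.atleast_2d(np.asarray(v2_tunings, dtype=float))
    n_ori = v1.shape[1]
    if n_ori != 8 or v2.shape[1] != 8:
        raise ValueError("full 8-orientation tuning required")
    if v1_grating_responses is None:
        if v1_cells is None:
            raise ValueError("need v1_grating_responses or v1_cells")
        v1_grating_responses = np.stack([grating_tuning(c) for c in v1_cells])
    g = np.asarray(v1_grating_responses, dtype=float)
    rng_meas = np.ptp(v2, axis=1)
    if np.any(rng_meas == 0):
        raise ValueError("degenerate measured response range (max == min)")

    n_pix = v2.shape[0]
    raw_pred = np.empty((n_pix, 8))
    pred_tf = np.empty((n_pix, 8))
    for k in range(8):
        train = np.delete(np.arange(8), k)
        wm = compute_weights(v1[:, train], v2[:, train])
        raw_all = wm.w.T @ g  # (n_pix, 8) pooled raw responses
        raw_pred[:, k] = raw_all[:, k]
        for j in range(n_pix):
            pred_tf[j, k], _ = _affine_calibrate(raw_all[j, train],
                                                 v2[j, train], raw_all[j, k])
    pred = np.empty((n_pix, 8))
    for j in range(n_pix):
        pred[j], _ = _affine_calibrate(raw_pred[j], v2[j], raw_pred[j])
    rel = np.abs(pred - v2) / rng_meas[:, None]
    rel_tf = np.abs(pred_tf - v2) / rng_meas[:, None]

    wm_full = compute_weights(v1, v2)
    raw_full = wm_full.w.T @ g
    po_err = np.empty(n_pix)
    hwhh_err = np.empty(n_pix)
    po_err_full = np.empty(n_pix)
    for j in range(n_pix):
        po_p, hw_p = _po_hwhh(pred[j])
        po_m, hw_m = _po_hwhh(v2[j])
        po_err[j] = _axial_err(po_p, po_m)
        hwhh_err[j] = abs(hw_p - hw_m)
        po_err_full[j] = _axial_err(vector_sum_po_single(raw_full[j]), po_m)
    return CVResult(predicted=pred, predicted_trainfit=pred_tf, measured=v2,
                    relative_error=rel, relative_error_trainfit=rel_tf,
                    po_abs_error=po_err, hwhh_abs_error=hwhh_err,
                    po_abs_error_full=po_err_full)
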