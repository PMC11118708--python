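"""Orientation-bias statistics for labeled V1 inputs.

All orientation data are axial (period 180 deg).  Circular statistics are
computed on doubled angles, following the standard Fisher treatment of
axial data: MRL = |mean(exp(i*2*theta))|, CSD = sqrt(-2*ln(MRL)).

Null models:

* pixel-resample — redraw as many map pixels as there are labeled cells,
  uniformly without replacement within the labeled-field contour;
* pattern-shift — rigidly translate the observed cell pattern by random
  integer pixel offsets keeping every cell inside the map;
* perfect like-to-like — the expected PO distribution when each cell's PO
  is the injection-site PO blurred by a wrapped Gaussian (FWHM 22.5 deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .oimaps import ORIENTATIONS, POMap

__all__ = [
    "PODistribution",
    "CircularStats",
    "NullEnsemble",
    "axial_distance",
    "po_histogram",
    "po_at_points",
    "fraction_within",
    "chisq_gof",
    "circ_stats",
    "pixel_resample_null",
    "pattern_shift_null",
    "like_to_like_expected",
    "like_to_like_sim",
    "ks_bonferroni",
]

BIN_WIDTH = 22.5
LIKE_TO_LIKE_FWHM = 22.5
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def axial_distance(a, b):
    """Smallest angular distance between two axial angles, in [0, 90]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


@dataclass
class PODistribution:
    """8-bin histogram of axial POs, bins centred on the stimulus
    orientations (width 22.5 deg, wrapping at 180)."""

    counts: np.ndarray
    n: int
    source: str = "cells"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(ORIENTATIONS),):
            raise ValueError("expected an 8-bin histogram")

    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def po_histogram(po_list, source: str = "cells") -> PODistribution:
    """Bin axial POs into the 8 stimulus-centred bins (axial wrap: a PO of
    179 deg falls in the 0-deg bin)."""
    po = np.asarray(po_list, dtype=float) % 180.0
    idx = np.round(po / BIN_WIDTH).astype(int) % len(ORIENTATIONS)
    counts = np.bincount(idx, minlength=len(ORIENTATIONS)).astype(float)
    return PODistribution(counts=counts, n=len(po), source=source)


def po_at_points(po_map: POMap, points) -> tuple[np.ndarray, np.ndarray]:
    """Look up per-point axial PO by nearest pixel.

    ``points`` are (n, 2) arrays of (x, y) == (col, row) coordinates.
    Returns (po values, indices of points dropped for lying on vessels).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cols = np.round(pts[:, 0]).astype(int)
    rows = np.round(pts[:, 1]).astype(int)
    h, w = po_map.po.shape
    if np.any((rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)):
        raise ValueError("point outside map bounds")
    on_vessel = po_map.vessel_mask[rows, cols]
    if on_vessel.all():
        raise ValueError("all points lie on vessels")
    dropped = np.flatnonzero(on_vessel)
    return po_map.po[rows[~on_vessel], cols[~on_vessel]], dropped


def fraction_within(cells_po, injection_po: float, tol: float = 22.5) -> float:
    """Fraction of cell POs within ``tol`` (axial distance) of the
    injection-site PO."""
    po = np.asarray(cells_po, dtype=float)
    if po.size == 0:
        raise ValueError("empty PO list")
    return float(np.mean(axial_distance(po, injection_po) <= tol))


@dataclass
class ChisqResult:
    statistic: float
    dof: int
    p: float
    merged_bins: int = 0


def chisq_gof(observed: PODistribution, expected: PODistribution) -> ChisqResult:
    """Pearson chi-square goodness of fit of an observed histogram against an
    expected one (rescaled to the observed total).

    dof = number of bins - 1 (7 for the standard 8-bin histograms).  Expected
    bins of zero mass are merged into their neighbour, reported via
    ``merged_bins``.
    """
    obs = observed.counts.astype(float)
    exp = expected.counts.astype(float)
    if exp.sum() <= 0:
        raise ValueError("expected histogram is empty")
    exp = exp / exp.sum() * obs.sum()
    merged = 0
    while np.any(exp == 0) and len(exp) > 1:
        i = int(np.flatnonzero(exp == 0)[0])
        j = i - 1 if i > 0 else i + 1
        exp[j] += exp[i]
        obs[j] += obs[i]
        exp = np.delete(exp, i)
        obs = np.delete(obs, i)
        merged += 1
    stat = float(np.sum((obs - exp) ** 2 / exp))
    dof = len(obs) - 1
    return ChisqResult(statistic=stat, dof=dof, p=float(sps.chi2.sf(stat, dof)),
                       merged_bins=merged)


@dataclass
class CircularStats:
    mrl: float
    csd: float        # radians, on doubled angles
    mean_po: float    # degrees, axial


def circ_stats(po_list) -> CircularStats:
    """Axial circular statistics via angle doubling (Fisher)."""
    po = np.asarray(po_list, dtype=float)
    if po.size == 0:
        raise ValueError("empty PO list")
    z = np.mean(np.exp(2j * np.deg2rad(po)))
    mrl = min(float(np.abs(z)), 1.0)
    csd = float(np.sqrt(-2.0 * np.log(mrl))) if mrl > 0 else np.inf
    mean_po = float(np.mod(np.rad2deg(np.angle(z)) / 2.0, 180.0))
    return CircularStats(mrl=mrl, csd=csd, mean_po=mean_po)


def _ensemble_stats(po_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.mean(np.exp(2j * np.deg2rad(po_draws)), axis=1)
    mrl = np.minimum(np.abs(z), 1.0)
    with np.errstate(divide="ignore"):
        csd = np.sqrt(-2.0 * np.log(np.maximum(mrl, 1e-300)))
    return mrl, csd


@dataclass
class NullEnsemble:
    mrl: np.ndarray
    csd: np.ndarray
    kind: str
    seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.mrl)

    def exceedance(self, observed: CircularStats) -> dict[str, float]:
        """Strict-inequality exceedance fractions F(MRL>obs), F(CSD<obs)."""
        return {"f_mrl_greater": float(np.mean(self.mrl > observed.mrl)),
                "f_csd_smaller": float(np.mean(self.csd < observed.csd))}


def pixel_resample_null(po_map: POMap, field_mask: np.ndarray, m: int,
                        n_rep: int = 1000,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None) -> NullEnsemble:
    """Resample ``m`` non-vessel pixels within the labeled-field contour,
    ``n_rep`` times without replacement, recording MRL/CSD per replicate."""
    rng = np.random.default_rng(seed) if rng is None else rng
    valid = np.asarray(field_mask, bool) & ~po_map.vessel_mask
    pool = po_map.po[valid]
    if pool.size < m:
        raise ValueError(f"contour holds {pool.size} usable pixels, need {m}")
    keys = rng.random((n_rep, pool.size))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    mrl, csd = _ensemble_stats(pool[idx])
    return NullEnsemble(mrl=mrl, csd=csd, kind="pixel_resample", seed=seed)


def admissible_shifts(cell_xy: np.ndarray, map_shape: tuple[int, int]):
    """Integer translation ranges keeping every cell inside the map.

    Returns (dx_range, dy_range) as inclusive (lo, hi) tuples.
    """
    pts = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    h, w = map_shape
    cols = np.round(pts[:, 0]).astype(int)
    rows = np.round(pts[:, 1]).astype(int)
    dx = (-cols.min(), w - 1 - cols.max())
    dy = (-rows.min(), h - 1 - rows.max())
    if dx[0] > dx[1] or dy[0] > dy[1]:
        raise ValueError("no admissible shift keeps the pattern in bounds")
    return dx, dy


def pattern_shift_null(po_map: POMap, cell_xy: np.ndarray,
                       n_shifts: int = 1500,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> NullEnsemble:
    """Rigidly translate the observed cell pattern by random integer-pixel
    offsets (relative layout preserved); cells landing on vessels are
    dropped within that replicate."""
    rng = np.random.default_rng(seed) if rng is None else rng
    pts = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    cols = np.round(pts[:, 0]).astype(int)
    rows = np.round(pts[:, 1]).astype(int)
    (dx0, dx1), (dy0, dy1) = admissible_shifts(pts, po_map.po.shape)
    dxs = rng.integers(dx0, dx1 + 1, size=n_shifts)
    dys = rng.integers(dy0, dy1 + 1, size=n_shifts)
    c = cols[None, :] + dxs[:, None]
    r = rows[None, :] + dys[:, None]
    po = po_map.po[r, c]
    vessel = po_map.vessel_mask[r, c]
    phase = np.exp(2j * np.deg2rad(po))
    phase[vessel] = 0.0
    kept = (~vessel).sum(axis=1)
    if np.any(kept == 0):
        raise ValueError("a replicate dropped every cell (all on vessels)")
    z = phase.sum(axis=1) / kept
    mrl = np.minimum(np.abs(z), 1.0)
    with np.errstate(divide="ignore"):
        csd = np.sqrt(-2.0 * np.log(np.maximum(mrl, 1e-300)))
    return NullEnsemble(mrl=mrl, csd=csd, kind="pattern_shift", seed=seed)


def _wrapped_gaussian_bin_probs(center_deg: float, sigma_deg: float,
                                n_wrap: int = 5) -> np.ndarray:
    """Probability mass of a wrapped (period 180) Gaussian in the 8 bins."""
    edges = ORIENTATIONS - BIN_WIDTH / 2.0
    lo = edges
    hi = edges + BIN_WIDTH
    p = np.zeros(len(ORIENTATIONS))
    for k in range(-n_wrap, n_wrap + 1):
        mu = center_deg + 180.0 * k
        p += (sps.norm.cdf(hi, loc=mu, scale=sigma_deg)
              - sps.norm.cdf(lo, loc=mu, scale=sigma_deg))
    return p


def like_to_like_expected(injection: PODistribution,
                          fwhm: float = LIKE_TO_LIKE_FWHM) -> PODistribution:
    """Expected cell-PO distribution under perfect like-to-like connectivity.

    A mixture over injection-site orientation columns: each column at
    orientation theta_i with weight alpha_i (the fraction of injection-site
    pixels preferring theta_i) contributes a wrapped Gaussian centred at
    theta_i with the given FWHM; the mixture is integrated over the 8
    stimulus bins.
    """
    alpha = injection.counts.astype(float)
    if alpha.sum() <= 0:
        raise ValueError("empty injection histogram")
    alpha = alpha / alpha.sum()
    sigma = fwhm / FWHM_TO_SIGMA
    p = np.zeros(len(ORIENTATIONS))
    for a, th in zip(alpha, ORIENTATIONS):
        if a == 0:
            continue
        if sigma <= 1e-9:  # delta limit
            comp = np.zeros(len(ORIENTATIONS))
            comp[int(round(th / BIN_WIDTH)) % 8] = 1.0
        else:
            comp = _wrapped_gaussian_bin_probs(th, sigma)
        p += a * comp
    p /= p.sum()
    return PODistribution(counts=p * injection.n, n=injection.n,
                          source="simulated")


def like_to_like_sim(injection: PODistribution, observed: PODistribution,
                     fwhm: float = LIKE_TO_LIKE_FWHM):
    """Chi-square test of the observed cell histogram against the perfect
    like-to-like expectation; a non-significant result is consistent with
    purely like-to-like connectivity.  Returns (expected, ChisqResult)."""
    expected = like_to_like_expected(injection, fwhm=fwhm)
    return expected, chisq_gof(observed, expected)


@dataclass
class KSDecision:
    statistic: float
    p: float
    reject: bool
    threshold: float
    degenerate: bool = False


def ks_bonferroni(observed, ensembles, family_alpha: float = 0.05) -> list[KSDecision]:
    """Two-sample KS test of ``observed`` against each sample in
    ``ensembles``; rejection at the Bonferroni-corrected threshold
    ``family_alpha / n_comparisons``.  Degenerate (constant) samples are
    flagged rather than tested."""
    ensembles = list(ensembles)
    if not ensembles:
        raise ValueError("need at least one comparison")
    thr = family_alpha / len(ensembles)
    obs = np.asarray(observed, dtype=float)
    out = []
    for samp in ensembles:
        samp = np.asarray(samp, dtype=float)
        if np.ptp(obs) == 0 and np.ptp(samp) == 0 and obs[0] == samp[0]:
            out.append(KSDecision(0.0, 1.0, False, thr, degenerate=True))
            continue
        res = sps.ks_2samp(obs, samp)
        out.append(KSDecision(float(res.statistic), float(res.pvalue),
                              bool(res.pvalue < thr), thr))
    return out
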