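"""Cortex-to-visual-field mapping via elliptic grid generation.

The labeled field on the cortex is outlined by four boundary polylines; one
side (the V1/V2 border) represents the vertical meridian.  A curvilinear
grid is laid over the region by solving the Winslow elliptic grid equations
(harmonic computational coordinates), boundary nodes being placed by
arc-length-uniform sampling of each side.  Visual-field coordinates are
assigned linearly along the grid indices at a fixed degree step, and each
labeled cell inherits the visual-field position of its nearest grid node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "RetinotopicOutline",
    "EllipticGrid",
    "CellAssignment",
    "generate_elliptic_grid",
    "resample_grid",
    "assign_cells",
    "degrees_from_stripes",
]

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 2_500_000


@dataclass
class RetinotopicOutline:
    """Four boundary polylines (pixel coords) plus visual-field extents.

    ``border`` is the V1/V2 border (vertical-meridian representation);
    ``opposite`` the facing side; ``low``/``high`` connect border->opposite
    at the two ends.  ``border`` and ``opposite`` run in the same direction
    (from their ``low`` end to their ``high`` end), as do ``low``/``high``
    (from border to opposite).  Extents are in degrees of visual angle:
    ``parallel_extent_deg`` along the border, ``orth_extent_deg`` across.
    """

    border: np.ndarray      # (n, 2) x,y pixel vertices
    opposite: np.ndarray
    low: np.ndarray
    high: np.ndarray
    parallel_extent_deg: float
    orth_extent_deg: float

    def __post_init__(self):
        for name in ("border", "opposite", "low", "high"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
                raise ValueError(f"side {name!r} must be an (n>=2, 2) polyline")
            setattr(self, name, v)
        if self.parallel_extent_deg <= 0 or self.orth_extent_deg <= 0:
            raise ValueError("degree extents must be positive")
        # corner consistency
        for a, b, tag in [(self.low[0], self.border[0], "low/border"),
                          (self.low[-1], self.opposite[0], "low/opposite"),
                          (self.high[0], self.border[-1], "high/border"),
                          (self.high[-1], self.opposite[-1], "high/opposite")]:
            if not np.allclose(a, b, atol=1e-6):
                raise ValueError(f"outline corners do not meet at {tag}")

    @classmethod
    def rectangle(cls, origin: tuple[float, float], width_px: float,
                  height_px: float, parallel_extent_deg: float,
                  orth_extent_deg: float) -> "RetinotopicOutline":
        """Axis-aligned rectangular outline; the border is the left edge
        (height is the border-parallel direction)."""
        x0, y0 = origin
        border = np.array([[x0, y0], [x0, y0 + height_px]])
        opposite = np.array([[x0 + width_px, y0], [x0 + width_px, y0 + height_px]])
        low = np.array([[x0, y0], [x0 + width_px, y0]])
        high = np.array([[x0, y0 + height_px], [x0 + width_px, y0 + height_px]])
        return cls(border, opposite, low, high, parallel_extent_deg, orth_extent_deg)


def _sample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    """n points at arc-length-uniform spacing along a polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate (zero-length) outline side")
    t = np.linspace(0.0, s[-1], n)
    return np.stack([np.interp(t, s, poly[:, 0]), np.interp(t, s, poly[:, 1])], axis=1)


def _transfinite(border, opposite, low, high):
    """Transfinite interpolation of the four sampled sides -> initial grid."""
    n_i, n_j = len(border), len(low)
    s = np.linspace(0, 1, n_i)[:, None, None]   # along border
    t = np.linspace(0, 1, n_j)[None, :, None]   # border -> opposite
    B = border[:, None, :]
    O = opposite[:, None, :]
    L = low[None, :, :]
    H = high[None, :, :]
    c00, c01 = border[0], opposite[0]
    c10, c11 = border[-1], opposite[-1]
    g = ((1 - t) * B + t * O + (1 - s) * L + s * H
         - ((1 - s) * (1 - t) * c00 + (1 - s) * t * c01
            + s * (1 - t) * c10 + s * t * c11))
    return g  # (n_i, n_j, 2)


@dataclass
class EllipticGrid:
    """Curvilinear grid over the outline; node (i, j) lives at cortex pixel
    ``xy[i, j]`` and visual-field position ``vf[i, j]`` (degrees).

    i runs along the V1/V2 border (parallel axis), j orthogonal to it.
    """

    xy: np.ndarray   # (n_i, n_j, 2) cortex pixels
    vf: np.ndarray   # (n_i, n_j, 2) degrees (parallel, orthogonal)
    parallel_extent_deg: float
    orth_extent_deg: float
    convergence_error: float
    iterations_used: int
    converged: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.xy.shape[:2]

    def cell_areas(self) -> np.ndarray:
        """Signed areas of the grid quadrilaterals (shoelace); uniform sign
        means no folding."""
        p00 = self.xy[:-1, :-1]
        p10 = self.xy[1:, :-1]
        p11 = self.xy[1:, 1:]
        p01 = self.xy[:-1, 1:]
        def cross(a, b):
            return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
        return 0.5 * (cross(p10 - p00, p11 - p00) + cross(p11 - p00, p01 - p00))


def _vf_coords(n_i, n_j, parallel_extent, orth_extent):
    res_i = parallel_extent / max(n_i - 1, 1)
    res_j = orth_extent / max(n_j - 1, 1)
    vi = np.arange(n_i) * res_i
    vj = np.arange(n_j) * res_j
    return np.stack(np.meshgrid(vi, vj, indexing="ij"), axis=-1)


def generate_elliptic_grid(outline: RetinotopicOutline, n_i: int, n_j: int,
                           tol: float = DEFAULT_TOL,
                           max_iter: int = 20_000) -> EllipticGrid:
    """Solve the Winslow elliptic grid equations over the outlined region.

    Boundary nodes are arc-length-uniform samples of each side (Dirichlet);
    the interior starts from transfinite interpolation and is relaxed by
    Jacobi iteration of the quasi-linear Winslow system until the maximum
    node displacement drops below ``tol`` (pixels) or ``max_iter`` sweeps
    (hard-capped at 2,500,000) are exhausted; non-convergence is flagged.
    """
    if n_i < 2 or n_j < 2:
        raise ValueError("grid needs at least 2 nodes per axis")
    max_iter = min(max_iter, DEFAULT_MAX_ITER)
    border = _sample_polyline(outline.border, n_i)
    opposite = _sample_polyline(outline.opposite, n_i)
    low = _sample_polyline(outline.low, n_j)
    high = _sample_polyline(outline.high, n_j)
    g = _transfinite(border, opposite, low, high)

    err = np.inf
    it = 0
    while it < max_iter:
        it += 1
        gi = 0.5 * (g[2:, 1:-1] - g[:-2, 1:-1])     # d/di
        gj = 0.5 * (g[1:-1, 2:] - g[1:-1, :-2])     # d/dj
        alpha = (gj ** 2).sum(-1)
        gamma = (gi ** 2).sum(-1)
        beta = (gi * gj).sum(-1)
        cross = (g[2:, 2:] - g[2:, :-2] - g[:-2, 2:] + g[:-2, :-2])
        new = (alpha[..., None] * (g[2:, 1:-1] + g[:-2, 1:-1])
               + gamma[..., None] * (g[1:-1, 2:] + g[1:-1, :-2])
               - 0.5 * beta[..., None] * cross)
        denom = 2.0 * (alpha + gamma)
        # degenerate metric (coincident nodes): keep old position
        ok = denom > 1e-30
        upd = g[1:-1, 1:-1].copy()
        upd[ok] = new[ok] / denom[ok, None]
        err = float(np.abs(upd - g[1:-1, 1:-1]).max()) if upd.size else 0.0
        g[1:-1, 1:-1] = upd
        if err < tol:
            break

    vf = _vf_coords(n_i, n_j, outline.parallel_extent_deg, outline.orth_extent_deg)
    return EllipticGrid(xy=g, vf=vf,
                        parallel_extent_deg=outline.parallel_extent_deg,
                        orth_extent_deg=outline.orth_extent_deg,
                        convergence_error=err, iterations_used=it,
                        converged=err < tol)


def resample_grid(grid: EllipticGrid, resolution_deg: float = 0.02) -> EllipticGrid:
    """Bilinear-resample node coordinates to a fixed degree step.

    The resampled shape is ``round(extent / resolution)`` nodes per axis,
    matching the convention that a 2.5 x 1.5 deg region at 0.02 deg yields a
    125 x 75 grid; visual-field spacing equals ``resolution_deg`` exactly.
    """
    if resolution_deg <= 0:
        raise ValueError("resolution must be positive")
    n_i = int(round(grid.parallel_extent_deg / resolution_deg))
    n_j = int(round(grid.orth_extent_deg / resolution_deg))
    if n_i < 2 or n_j < 2:
        raise ValueError("resolution too coarse for the region extents")
    oi, oj = grid.shape
    ci = np.linspace(0, oi - 1, n_i)
    cj = np.linspace(0, oj - 1, n_j)
    CI, CJ = np.meshgrid(ci, cj, indexing="ij")
    xy = np.stack([map_coordinates(grid.xy[..., k], [CI, CJ], order=1)
                   for k in range(2)], axis=-1)
    vi = np.arange(n_i) * resolution_deg
    vj = np.arange(n_j) * resolution_deg
    vf = np.stack(np.meshgrid(vi, vj, indexing="ij"), axis=-1)
    return EllipticGrid(xy=xy, vf=vf,
                        parallel_extent_deg=grid.parallel_extent_deg,
                        orth_extent_deg=grid.orth_extent_deg,
                        convergence_error=grid.convergence_error,
                        iterations_used=grid.iterations_used,
                        converged=grid.converged)


@dataclass
class CellAssignment:
    """Nearest-node assignment of labeled cells to visual-field positions."""

    node_index: np.ndarray   # (n_cells, 2) int (i, j)
    vf_position: np.ndarray  # (n_cells, 2) degrees
    distance_px: np.ndarray  # (n_cells,) cortex distance to the node


def assign_cells(cell_xy: np.ndarray, grid: EllipticGrid,
                 chunk: int = 512) -> CellAssignment:
    """Assign each cell to its Euclidean-nearest grid node in cortex pixels.

    Ties are broken deterministically toward the smallest (i, j) in
    lexicographic order (first minimum in row-major node order).
    """
    nodes = grid.xy.reshape(-1, 2)
    if nodes.size == 0:
        raise ValueError("empty grid")
    cells = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    n_j = grid.shape[1]
    idx = np.empty(len(cells), dtype=int)
    dist = np.empty(len(cells))
    for a in range(0, len(cells), chunk):
        b = min(a + chunk, len(cells))
        d2 = ((cells[a:b, None, :] - nodes[None, :, :]) ** 2).sum(-1)
        k = d2.argmin(axis=1)  # first occurrence == lexicographic smallest
        idx[a:b] = k
        dist[a:b] = np.sqrt(d2[np.arange(b - a), k])
    ij = np.stack([idx // n_j, idx % n_j], axis=1)
    vf = grid.vf[ij[:, 0], ij[:, 1]]
    return CellAssignment(node_index=ij, vf_position=vf, distance_px=dist)


def degrees_from_stripes(side_span_px: float, stripe_positions_px: np.ndarray,
                         stripe_period_deg: float) -> float:
    """Express a cortical extent in visual degrees from retinotopic stripes.

    ``stripe_positions_px`` are positions of successive stripe centers
    (one per period) along the axis; the extent is the number of periods
    spanned by the side — fractional periods interpolated linearly from the
    mean inter-stripe spacing — times the stripe period in degrees.
    """
    t = np.sort(np.asarray(stripe_positions_px, dtype=float))
    if t.size < 2:
        raise ValueError("need >= 2 stripe crossings to estimate the period")
    period_px = float(np.diff(t).mean())
    if period_px <= 0:
        raise ValueError("degenerate stripe spacing")
    return float(side_span_px / period_px * stripe_period_deg)
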