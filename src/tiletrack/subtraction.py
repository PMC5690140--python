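"""Background subtraction via per-tile linear intensity maps.

After tile matching, every good tile gets an ordinary-least-squares linear
intensity transform P ≈ a·D + b between the DRR tile and the projection
tile. The bad (tumor) tile's transform cannot be trusted — the tumor is in
P but not in D — so its coefficients are interpolated from the
surrounding tile centers. Coefficients are then bilinearly interpolated
from the tile centers down to pixel level (clamped outside the outermost
centers), giving continuous gain/offset fields with no tile-induced
boundaries. Applying the fields to the DRR and subtracting from the
projection leaves a residual dominated by the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .images import Image2D, as_image_array
from .tiles import TileConfig, TileMatchResult

__all__ = [
    "TileFit",
    "IntensityMapGrid",
    "fit_tile_intensity_map",
    "build_map_grid",
    "subtract_background",
]


class TileFit(NamedTuple):
    """OLS linear intensity map P ≈ a·D + b over one tile."""

    a: float
    b: float
    degenerate: bool = False


def fit_tile_intensity_map(P_tile, D_tile) -> TileFit:
    """Closed-form least-squares gain/offset between congruent tiles.

    A constant (zero-variance) DRR tile cannot determine a gain; the fit
    degrades to a = 0, b = mean(P) and is flagged degenerate.
    """
    p = np.asarray(P_tile, dtype=float).ravel()
    d = np.asarray(D_tile, dtype=float).ravel()
    if p.shape != d.shape:
        raise ValueError("tiles must be congruent")
    dm = d.mean()
    dd = d - dm
    var = float(dd @ dd)
    if var == 0.0:
        return TileFit(a=0.0, b=float(p.mean()), degenerate=True)
    a = float(dd @ (p - p.mean())) / var
    return TileFit(a=a, b=float(p.mean() - a * dm), degenerate=False)


@dataclass
class IntensityMapGrid:
    """Per-tile linear transforms and their pixel-level interpolations.

    ``a_grid``/``b_grid`` are indexed [v, u]; ``centers_row``/``centers_col``
    are the projection-frame tile centers; ``a_field``/``b_field`` are the
    bilinearly interpolated pixel coefficient fields on the projection
    grid. ``bad_tile`` marks the tile whose coefficients were interpolated
    from its neighbors.
    """

    config: TileConfig
    a_grid: np.ndarray
    b_grid: np.ndarray
    centers_row: np.ndarray
    centers_col: np.ndarray
    bad_tile: tuple[int, int]
    degenerate: np.ndarray
    a_field: np.ndarray
    b_field: np.ndarray


def _interp_axis(coords: np.ndarray, centers: np.ndarray):
    if centers.size == 1:
        z = np.zeros(coords.size, dtype=int)
        return z, z, np.ones(coords.size)
    idx = np.clip(np.searchsorted(centers, coords) - 1, 0, centers.size - 2)
    w = (coords - centers[idx]) / (centers[idx + 1] - centers[idx])
    return idx, idx + 1, np.clip(w, 0.0, 1.0)  # clamp = constant extrapolation


def _bilinear_field(grid: np.ndarray, centers_row, centers_col, shape) -> np.ndarray:
    rows, cols = shape
    i0, i1, wy = _interp_axis(np.arange(rows, dtype=float), centers_row)
    j0, j1, wx = _interp_axis(np.arange(cols, dtype=float), centers_col)
    WY, WX = wy[:, None], wx[None, :]
    return (
        (1 - WY) * (1 - WX) * grid[i0[:, None], j0[None, :]]
        + (1 - WY) * WX * grid[i0[:, None], j1[None, :]]
        + WY * (1 - WX) * grid[i1[:, None], j0[None, :]]
        + WY * WX * grid[i1[:, None], j1[None, :]]
    )


def build_map_grid(P, D, match: TileMatchResult) -> IntensityMapGrid:
    """Fit all good tiles, interpolate the bad tile, build pixel fields.

    The bad tile's (a, b) is the inverse-distance-weighted mean of its
    available non-degenerate 4-neighbors — for an interior tile (equal
    distances) this is exactly the bilinear interpolation of the four
    surrounding centers. More than one degenerate neighbor of the bad tile
    leaves too little support and is rejected.
    """
    Pa, Da = as_image_array(P), as_image_array(D)
    cfg = match.config
    U, V = cfg.U, cfg.V
    a = np.zeros((V, U))
    b = np.zeros((V, U))
    degen = np.zeros((V, U), dtype=bool)
    for v in range(V):
        for u in range(U):
            fit = fit_tile_intensity_map(
                Pa[cfg.proj_tile_slices(u, v)], Da[cfg.drr_tile_slices(u, v)]
            )
            a[v, u], b[v, u], degen[v, u] = fit.a, fit.b, fit.degenerate

    bu, bv = match.bad_tile
    centers_row = np.array([cfg.tile_center_px(0, v)[0] for v in range(V)])
    centers_col = np.array([cfg.tile_center_px(u, 0)[1] for u in range(U)])

    neighbors = [
        (bu + du, bv + dv)
        for du, dv in ((-1, 0), (1, 0), (0, -1), (0, 1))
        if 0 <= bu + du < U and 0 <= bv + dv < V
    ]
    n_degen = sum(degen[nv, nu] for nu, nv in neighbors)
    if n_degen > 1:
        raise ValueError(
            f"{n_degen} degenerate tiles adjacent to the bad tile "
            f"{match.bad_tile}; intensity map cannot be interpolated reliably"
        )
    usable = [(nu, nv) for nu, nv in neighbors if not degen[nv, nu]]
    if not usable:
        raise ValueError("bad tile has no usable neighbor")
    c_bad = np.array(cfg.tile_center_px(bu, bv))
    weights = np.array(
        [1.0 / np.linalg.norm(np.array(cfg.tile_center_px(nu, nv)) - c_bad) for nu, nv in usable]
    )
    weights /= weights.sum()
    a[bv, bu] = sum(w * a[nv, nu] for w, (nu, nv) in zip(weights, usable))
    b[bv, bu] = sum(w * b[nv, nu] for w, (nu, nv) in zip(weights, usable))

    a_field = _bilinear_field(a, centers_row, centers_col, Pa.shape)
    b_field = _bilinear_field(b, centers_row, centers_col, Pa.shape)
    return IntensityMapGrid(
        config=cfg,
        a_grid=a,
        b_grid=b,
        centers_row=centers_row,
        centers_col=centers_col,
        bad_tile=(bu, bv),
        degenerate=degen,
        a_field=a_field,
        b_field=b_field,
    )


def subtract_background(P, D, grid: IntensityMapGrid) -> Image2D:
    """Residual = P − (a·D_aligned + b), pixelwise.

    The DRR is first aligned to the projection frame by the relative tile
    offset (d − p) of the matched configuration; pixels with no DRR
    counterpart are set to 0. With identical offsets this is simply
    P − (a·D + b).
    """
    Pa, Da = as_image_array(P), as_image_array(D)
    if Pa.shape != grid.a_field.shape:
        raise ValueError("projection and coefficient fields differ in shape")
    cfg = grid.config
    dr = cfg.d_v - cfg.p_v
    dc = cfg.d_u - cfg.p_u
    aligned = np.zeros_like(Pa)
    rows, cols = Pa.shape
    r0, r1 = max(0, -dr), min(rows, Da.shape[0] - dr)
    c0, c1 = max(0, -dc), min(cols, Da.shape[1] - dc)
    if r1 > r0 and c1 > c0:
        aligned[r0:r1, c0:c1] = Da[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    residual = Pa - (grid.a_field * aligned + grid.b_field)
    if r0 > 0 or c0 > 0 or r1 < rows or c1 < cols:
        mask = np.zeros_like(Pa, dtype=bool)
        mask[r0:r1, c0:c1] = True
        residual = np.where(mask, residual, 0.0)
    pitch = P.pixel_pitch_mm if isinstance(P, Image2D) else 1.0
    return Image2D(residual, pixel_pitch_mm=pitch, kind="residual")
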