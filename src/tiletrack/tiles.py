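"""Tile-partitioned NCC matching with tile-shift optimization.

The projection P and the background DRR D are divided into the same U×V
matrix of non-overlapping tiles; the tile grid starts at pixel (p_u, p_v)
on the projection and (d_u, d_v) on the DRR. Per-tile similarity is the
normalized cross-correlation

    s(u,v) = Σ (P - P̄)(D - D̄) / sqrt(Σ (P - P̄)² · Σ (D - D̄)²)

over the tile, and the total similarity S is the mean of the tile scores.
Because the tumor moves on the projection but is absent from the
background DRR, one region always matches badly; shifting the tile-grid
start point relocates tile boundaries until that discrepancy falls inside
a single *bad tile*, which is excluded from S. The shift maximizing the
bad-tile-excluded S aligns the remaining (background) tiles as well as
possible and localizes the tumor to roughly one tile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .images import as_image_array

__all__ = [
    "TileConfig",
    "TileMatchResult",
    "make_tile_config",
    "recommended_tile_size",
    "tile_ncc",
    "ncc_matrix",
    "total_ncc",
    "find_bad_tile",
    "optimize_tile_shift",
]


@dataclass(frozen=True)
class TileConfig:
    """A U×V grid of non-overlapping tiles on a projection/DRR pair.

    Offsets are the pixel of the first tile's top-left corner: (p_u, p_v)
    on the projection, (d_u, d_v) on the DRR, with u = columns and
    v = rows.
    """

    U: int = 3
    V: int = 3
    tile_width: int = 168
    tile_height: int = 168
    p_u: int = 0
    p_v: int = 0
    d_u: int = 0
    d_v: int = 0

    def __post_init__(self) -> None:
        if self.U < 1 or self.V < 1:
            raise ValueError("tile grid must be at least 1x1")
        if self.tile_width < 1 or self.tile_height < 1:
            raise ValueError("tile size must be positive")
        if min(self.p_u, self.p_v, self.d_u, self.d_v) < 0:
            raise ValueError("tile offsets must be non-negative")

    def fits(self, proj_shape, drr_shape) -> bool:
        ph, pw = proj_shape
        dh, dw = drr_shape
        return (
            self.p_u + self.U * self.tile_width <= pw
            and self.p_v + self.V * self.tile_height <= ph
            and self.d_u + self.U * self.tile_width <= dw
            and self.d_v + self.V * self.tile_height <= dh
        )

    def proj_tile_slices(self, u: int, v: int) -> tuple[slice, slice]:
        r0 = self.p_v + v * self.tile_height
        c0 = self.p_u + u * self.tile_width
        return slice(r0, r0 + self.tile_height), slice(c0, c0 + self.tile_width)

    def drr_tile_slices(self, u: int, v: int) -> tuple[slice, slice]:
        r0 = self.d_v + v * self.tile_height
        c0 = self.d_u + u * self.tile_width
        return slice(r0, r0 + self.tile_height), slice(c0, c0 + self.tile_width)

    def tile_center_px(self, u: int, v: int) -> tuple[float, float]:
        """Center (row, col) of projection tile (u, v), pixel-center units."""
        rs, cs = self.proj_tile_slices(u, v)
        return (rs.start + rs.stop - 1) / 2.0, (cs.start + cs.stop - 1) / 2.0


def recommended_tile_size(tumor_extent_px: float, factor: float = 1.35) -> int:
    """Tile size from tumor size: ceil(factor × extent), clamped to the
    1.2–1.5× guidance so the tumor fits within a single tile."""
    lo = int(np.ceil(1.2 * tumor_extent_px))
    hi = int(np.floor(1.5 * tumor_extent_px))
    size = int(np.ceil(factor * tumor_extent_px))
    return min(max(size, lo), max(hi, lo))


def make_tile_config(
    image_shape,
    U: int = 3,
    V: int = 3,
    tile_size: int | tuple[int, int] | None = None,
    p_offset: tuple[int, int] = (0, 0),
    d_offset: tuple[int, int] = (0, 0),
    tumor_extent_px: float | None = None,
) -> TileConfig:
    """Build a valid tile configuration for images of ``image_shape``.

    ``tile_size`` may be an int (square) or (width, height); when omitted
    it is derived from ``tumor_extent_px`` via :func:`recommended_tile_size`.
    """
    if tile_size is None:
        if tumor_extent_px is None:
            raise ValueError("give tile_size or tumor_extent_px")
        tile_size = recommended_tile_size(tumor_extent_px)
        # a derived size is advisory: clamp it so the U×V grid fits
        h, w = image_shape
        tile_size = min(
            tile_size, (w - int(p_offset[0])) // U, (h - int(p_offset[1])) // V
        )
    if np.isscalar(tile_size):
        tw = th = int(tile_size)
    else:
        tw, th = (int(t) for t in tile_size)
    cfg = TileConfig(
        U=U, V=V, tile_width=tw, tile_height=th,
        p_u=int(p_offset[0]), p_v=int(p_offset[1]),
        d_u=int(d_offset[0]), d_v=int(d_offset[1]),
    )
    if not cfg.fits(image_shape, image_shape):
        h, w = image_shape
        max_pu = w - U * tw
        max_pv = h - V * th
        raise ValueError(
            f"tiles exceed image bounds; maximal feasible offsets are "
            f"p_u={max(max_pu, 0)}, p_v={max(max_pv, 0)} "
            f"(negative grid extent means the tiles cannot fit at all)"
        )
    return cfg


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0.0:
        return 0.0  # constant tile carries no matching evidence
    return float((da * db).sum() / denom)


def tile_ncc(P, D, config: TileConfig, u: int, v: int) -> float:
    """Normalized cross-correlation between projection tile (u,v) and the
    corresponding DRR tile. Zero-variance tiles score 0 by convention."""
    Pa, Da = as_image_array(P), as_image_array(D)
    if not (0 <= u < config.U and 0 <= v < config.V):
        raise ValueError("tile index out of range")
    if not config.fits(Pa.shape, Da.shape):
        raise ValueError("tile configuration does not fit the images")
    return _ncc(Pa[config.proj_tile_slices(u, v)], Da[config.drr_tile_slices(u, v)])


def ncc_matrix(P, D, config: TileConfig) -> np.ndarray:
    """All per-tile NCC scores as an array s[v, u] (rows = v, cols = u)."""
    Pa, Da = as_image_array(P), as_image_array(D)
    if not config.fits(Pa.shape, Da.shape):
        raise ValueError("tile configuration does not fit the images")
    s = np.empty((config.V, config.U))
    for v in range(config.V):
        for u in range(config.U):
            s[v, u] = _ncc(
                Pa[config.proj_tile_slices(u, v)], Da[config.drr_tile_slices(u, v)]
            )
    return s


def find_bad_tile(s_matrix: np.ndarray) -> tuple[int, int]:
    """Index (u, v) of the minimum tile score; ties break to the first
    occurrence in row-major (v, then u) order."""
    s = np.asarray(s_matrix)
    v, u = np.unravel_index(np.argmin(s), s.shape)
    return int(u), int(v)


def total_ncc(s_matrix: np.ndarray, exclude_bad: bool = True) -> float:
    """Total similarity S: mean tile score, optionally dropping the single
    worst (bad) tile from the average."""
    s = np.asarray(s_matrix, dtype=float)
    if exclude_bad:
        if s.size <= 1:
            raise ValueError("bad-tile exclusion needs more than one tile")
        u, v = find_bad_tile(s)
        return float((s.sum() - s[v, u]) / (s.size - 1))
    return float(s.mean())


@dataclass
class TileMatchResult:
    """Outcome of tile matching at one configuration."""

    config: TileConfig
    s_matrix: np.ndarray  # s[v, u]
    bad_tile: tuple[int, int]  # (u, v)
    total: float  # bad-tile-excluded mean unless exclusion was off
    exclude_bad: bool = True


def _evaluate(P, D, config: TileConfig, exclude_bad: bool) -> TileMatchResult:
    s = ncc_matrix(P, D, config)
    return TileMatchResult(
        config=config,
        s_matrix=s,
        bad_tile=find_bad_tile(s),
        total=total_ncc(s, exclude_bad=exclude_bad),
        exclude_bad=exclude_bad,
    )


def optimize_tile_shift(
    P,
    D,
    base: TileConfig,
    search_range_px: int | None = None,
    step_px: int | None = None,
    search_drr: bool = False,
    exclude_bad: bool = True,
) -> TileMatchResult:
    """Exhaustively search tile-grid start offsets for the best total NCC.

    The grid start is shifted on both images together — candidate common
    offsets ``k·step`` for k·step in [0, search_range), added to both the
    projection and DRR bases — which relocates the tile boundaries over
    the registered image pair until the tumor discrepancy falls inside a
    single (excluded) tile. By default the search spans one tile period
    (``tile_size``) in steps of ``tile_size // 8``, covering every
    distinct tiling. With ``search_drr`` an additional independent offset
    of the DRR grid is searched as well, which scans relative
    (registration) shifts between the two images. Candidates whose tiles
    would extend past either image are dropped (never padded). The best
    configuration (ties: lexicographically smallest offsets) is returned
    with its score matrix, bad tile and total S.
    """
    Pa, Da = as_image_array(P), as_image_array(D)
    if search_range_px is None:
        search_range_px = min(base.tile_width, base.tile_height)
    if step_px is None:
        step_px = max(min(base.tile_width, base.tile_height) // 8, 1)
    if search_range_px < 1 or step_px < 1:
        raise ValueError("search range and step must be positive")
    shifts = range(0, search_range_px, step_px)
    d_shifts = shifts if search_drr else [0]

    best: TileMatchResult | None = None
    best_key: tuple | None = None
    n_valid = 0
    for dv in d_shifts:
        for du in d_shifts:
            for pv in shifts:
                for pu in shifts:
                    cfg = replace(
                        base,
                        p_u=base.p_u + pu, p_v=base.p_v + pv,
                        d_u=base.d_u + pu + du, d_v=base.d_v + pv + dv,
                    )
                    if not cfg.fits(Pa.shape, Da.shape):
                        continue
                    n_valid += 1
                    res = _evaluate(Pa, Da, cfg, exclude_bad)
                    key = (-res.total, du, dv, pu, pv)
                    if best_key is None or key < best_key:
                        best, best_key = res, key
    if best is None:
        raise ValueError("no valid tile configuration in the search grid")
    if n_valid == 0:
        raise ValueError("empty search grid")
    return best
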