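"""Per-tile linear intensity maps, bilinear coefficient fields, subtraction."""

import numpy as np
import pytest

from tiletrack import (
    TileConfig,
    TileMatchResult,
    build_map_grid,
    fit_tile_intensity_map,
    ncc_matrix,
    subtract_background,
    total_ncc,
)
from tiletrack.tiles import find_bad_tile


def make_match(P, D, cfg, bad_tile=None):
    s = ncc_matrix(P, D, cfg)
    if bad_tile is not None:
        bu, bv = bad_tile
        s = s.copy()
        s[bv, bu] = -2.0  # force the designated bad tile
    return TileMatchResult(
        config=cfg,
        s_matrix=s,
        bad_tile=find_bad_tile(s),
        total=total_ncc(s, exclude_bad=True),
    )


def normal_equations_oracle(p, d):
    """Independent OLS via the 2x2 normal equations (test oracle)."""
    A = np.array([[np.sum(d * d), np.sum(d)], [np.sum(d), d.size]])
    rhs = np.array([np.sum(d * p), np.sum(p)])
    a, b = np.linalg.solve(A, rhs)
    return a, b


class TestFitTileIntensityMap:
    def test_identity_and_exact_linear_relation(self, rng):
        D = rng.random((20, 20))
        assert fit_tile_intensity_map(D, D)[:2] == pytest.approx((1.0, 0.0), abs=1e-10)
        a, b, degen = fit_tile_intensity_map(2.0 * D + 5.0, D)
        assert (a, b) == pytest.approx((2.0, 5.0), abs=1e-10)
        assert not degen

    def test_noisy_relation_recovers_gain_and_matches_normal_equations(self, rng):
        D = rng.random((168, 168)) * 100.0
        P = 1.3 * D - 40.0 + rng.normal(0, 1.0, D.shape)  # 1% of the range
        fit = fit_tile_intensity_map(P, D)
        assert fit.a == pytest.approx(1.3, rel=0.01)
        a_o, b_o = normal_equations_oracle(P.ravel(), D.ravel())
        assert fit.a == pytest.approx(a_o, abs=1e-12)
        assert fit.b == pytest.approx(b_o, abs=1e-10)

    def test_constant_drr_tile_degenerates_to_projection_mean(self, rng):
        P = rng.random((10, 10))
        fit = fit_tile_intensity_map(P, np.full((10, 10), 3.0))
        assert fit.degenerate
        assert fit.a == 0.0 and fit.b == pytest.approx(P.mean())

    def test_incongruent_tiles_rejected(self):
        with pytest.raises(ValueError):
            fit_tile_intensity_map(np.zeros((4, 4)), np.zeros((5, 5)))


def piecewise_affine_pair(rng, cfg, gains, offsets):
    """P equal per tile to gains[v,u]*D + offsets[v,u], D textured."""
    D = rng.random((cfg.V * cfg.tile_height, cfg.U * cfg.tile_width)) + 0.5
    P = np.empty_like(D)
    for v in range(cfg.V):
        for u in range(cfg.U):
            rs, cs = cfg.proj_tile_slices(u, v)
            P[rs, cs] = gains[v, u] * D[rs, cs] + offsets[v, u]
    return P, D


class TestBuildMapGrid:
    def test_uniform_transform_gives_constant_fields(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=20, tile_height=20)
        D = rng.random((60, 60))
        P = 1.5 * D - 10.0
        grid = build_map_grid(P, D, make_match(P, D, cfg, bad_tile=(1, 1)))
        assert np.allclose(grid.a_field, 1.5, atol=1e-9)
        assert np.allclose(grid.b_field, -10.0, atol=1e-8)

    def test_field_midpoint_between_adjacent_centers_is_the_mean(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=20, tile_height=20)
        gains = np.array([[1.0, 2.0, 3.0]] * 3, dtype=float)
        P, D = piecewise_affine_pair(rng, cfg, gains, np.zeros((3, 3)))
        grid = build_map_grid(P, D, make_match(P, D, cfg, bad_tile=(1, 2)))
        # centers of tiles (0,0) and (1,0) are 20 px apart in column; the
        # exact midpoint (19.5) falls between pixels, but the field is
        # linear there, so the two straddling pixels average to the
        # midpoint value (gain (1.0 + 2.0)/2 = 1.5)
        r = int(grid.centers_row[0])
        c_mid = (grid.centers_col[0] + grid.centers_col[1]) / 2.0
        lo, hi = int(np.floor(c_mid)), int(np.ceil(c_mid))
        assert (grid.a_field[r, lo] + grid.a_field[r, hi]) / 2 == pytest.approx(1.5, abs=1e-9)

    def test_interior_bad_tile_interpolates_mean_of_four_neighbors(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=20, tile_height=20)
        gains = np.ones((3, 3))
        gains[0, 1], gains[2, 1], gains[1, 0], gains[1, 2] = 1.0, 2.0, 3.0, 4.0
        gains[1, 1] = 99.0  # tumor tile: its own fit must be discarded
        P, D = piecewise_affine_pair(rng, cfg, gains, np.zeros((3, 3)))
        grid = build_map_grid(P, D, make_match(P, D, cfg, bad_tile=(1, 1)))
        assert grid.a_grid[1, 1] == pytest.approx(2.5, abs=1e-9)

    def test_bad_tile_interpolation_is_a_convex_combination(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=20, tile_height=20)
        gains = 1.0 + rng.random((3, 3))
        P, D = piecewise_affine_pair(rng, cfg, gains, rng.random((3, 3)))
        for bad in [(0, 0), (2, 0), (1, 1), (2, 2)]:
            grid = build_map_grid(P, D, make_match(P, D, cfg, bad_tile=bad))
            bu, bv = bad
            neigh = [
                gains[bv + dv, bu + du]
                for du, dv in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= bu + du < 3 and 0 <= bv + dv < 3
            ]
            assert min(neigh) - 1e-9 <= grid.a_grid[bv, bu] <= max(neigh) + 1e-9

    def test_fields_equal_grid_values_exactly_at_tile_centers(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=21, tile_height=21)
        gains = 1.0 + rng.random((3, 3))
        P, D = piecewise_affine_pair(rng, cfg, gains, rng.random((3, 3)))
        grid = build_map_grid(P, D, make_match(P, D, cfg, bad_tile=(0, 0)))
        for v in range(3):
            for u in range(3):
                r, c = cfg.tile_center_px(u, v)
                assert grid.a_field[int(r), int(c)] == grid.a_grid[v, u]
                assert grid.b_field[int(r), int(c)] == grid.b_grid[v, u]

    def test_pixel_fields_are_continuous(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=20, tile_height=20)
        gains = 1.0 + 2.0 * rng.random((3, 3))
        P, D = piecewise_affine_pair(rng, cfg, gains, rng.random((3, 3)))
        grid = build_map_grid(P, D, make_match(P, D, cfg, bad_tile=(1, 1)))
        bound = np.ptp(grid.a_grid) / 20.0 + 1e-9
        assert np.abs(np.diff(grid.a_field, axis=0)).max() <= bound
        assert np.abs(np.diff(grid.a_field, axis=1)).max() <= bound

    def test_degenerate_neighbors_of_bad_tile_rejected(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=10, tile_height=10)
        D = rng.random((30, 30))
        D[0:10, 10:20] = 5.0  # tile (1,0) constant
        D[10:20, 0:10] = 7.0  # tile (0,1) constant
        P = 2.0 * D + 1.0
        with pytest.raises(ValueError, match="degenerate"):
            build_map_grid(P, D, make_match(P, D, cfg, bad_tile=(0, 0)))


class TestSubtractBackground:
    def test_global_affine_relation_subtracts_to_zero(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=30, tile_height=30)
        D = rng.random((90, 90)) * 50.0
        P = 1.3 * D - 7.0
        grid = build_map_grid(P, D, make_match(P, D, cfg))
        res = subtract_background(P, D, grid)
        assert np.max(np.abs(res.data)) < 1e-10 * np.ptp(P)

    def test_additive_disc_with_identity_maps_is_returned_exactly(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=30, tile_height=30)
        D = rng.random((90, 90))
        disc = np.zeros_like(D)
        yy, xx = np.mgrid[0:90, 0:90]
        disc[(yy - 45) ** 2 + (xx - 45) ** 2 <= 100] = 3.0
        P = D + disc
        grid = build_map_grid(P, D, make_match(P, D, cfg))  # bad tile = disc tile
        res = subtract_background(P, D, grid)
        outside = disc == 0.0
        # the disc tile's map is interpolated from clean neighbors (≈ identity)
        assert np.max(np.abs(res.data - disc)) < 0.05
        assert np.max(np.abs(res.data[outside])) < 0.05

    def test_varying_gains_with_disc_leaves_energy_in_the_disc(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=30, tile_height=30)
        # smooth global gain/offset fields (bilinear between tile centers)
        yy, xx = np.mgrid[0:90, 0:90]
        a_true = 1.0 + 0.3 * xx / 89.0 + 0.1 * yy / 89.0
        b_true = 5.0 - 2.0 * yy / 89.0
        D = rng.random((90, 90)) * 20.0 + 10.0
        disc = np.zeros_like(D)
        disc[(yy - 45) ** 2 + (xx - 45) ** 2 <= 100] = 30.0
        P = a_true * D + b_true + disc
        grid = build_map_grid(P, D, make_match(P, D, cfg))
        res = subtract_background(P, D, grid).data
        inside = disc > 0
        e_in = np.sum(res[inside] ** 2)
        e_out = np.sum(res[~inside] ** 2)
        assert e_out <= 0.05 * e_in

    def test_residual_linear_in_projection_for_fixed_maps(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=30, tile_height=30)
        D = rng.random((90, 90)) * 10.0
        P1 = 1.2 * D + rng.normal(0, 0.1, D.shape)
        P2 = rng.normal(0, 0.5, D.shape)
        grid = build_map_grid(P1, D, make_match(P1, D, cfg))
        r1 = subtract_background(P1, D, grid).data
        r12 = subtract_background(P1 + P2, D, grid).data
        assert np.allclose(r12 - r1, P2, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        cfg = TileConfig(U=3, V=3, tile_width=30, tile_height=30)
        D = rng.random((90, 90))
        P = 2.0 * D
        grid = build_map_grid(P, D, make_match(P, D, cfg))
        with pytest.raises(ValueError):
            subtract_background(P[:80, :80], D[:80, :80], grid)
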