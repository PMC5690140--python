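"""Tile NCC, total similarity, bad-tile exclusion, shift optimization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from tiletrack import (
    TileConfig,
    find_bad_tile,
    make_tile_config,
    ncc_matrix,
    optimize_tile_shift,
    recommended_tile_size,
    tile_ncc,
    total_ncc,
)


def direct_ncc_oracle(P, D):
    """Element-wise transcription of the tile NCC formula (test oracle):
    s = Σ (P−P̄)(D−D̄) / sqrt(Σ (P−P̄)² · Σ (D−D̄)²)."""
    num = 0.0
    for x in range(P.shape[0]):
        for y in range(P.shape[1]):
            num += (P[x, y] - P.mean()) * (D[x, y] - D.mean())
    den_p = sum((P[x, y] - P.mean()) ** 2 for x in range(P.shape[0]) for y in range(P.shape[1]))
    den_d = sum((D[x, y] - D.mean()) ** 2 for x in range(P.shape[0]) for y in range(P.shape[1]))
    return num / np.sqrt(den_p * den_d)


def disc_fixture(seed, tile=40, junction=(80, 80), amp_sigmas=10.0):
    """P = D + bright disc (radius 0.4·tile) centered on a 4-corner tile
    junction of the base 3×3 grid, on a smooth textured background."""
    rng = np.random.default_rng(seed)
    D = gaussian_filter(rng.normal(0, 1, (160, 160)), 3.0)
    P = D.copy()
    yy, xx = np.mgrid[0:160, 0:160]
    disc = (yy - junction[0]) ** 2 + (xx - junction[1]) ** 2 <= (0.4 * tile) ** 2
    P[disc] += amp_sigmas * D.std()
    base = TileConfig(U=3, V=3, tile_width=tile, tile_height=tile)
    return P, D, base


def brute_force_shift_scan(P, D, base, search_range, step):
    """Independent exhaustive scan over projection offsets (test oracle)."""
    best = None
    for pv in range(0, search_range, step):
        for pu in range(0, search_range, step):
            # common shift of both grids: boundaries move, correspondence kept
            cfg = TileConfig(
                U=base.U, V=base.V,
                tile_width=base.tile_width, tile_height=base.tile_height,
                p_u=base.p_u + pu, p_v=base.p_v + pv,
                d_u=base.d_u + pu, d_v=base.d_v + pv,
            )
            if cfg.p_u + cfg.U * cfg.tile_width > P.shape[1]:
                continue
            if cfg.p_v + cfg.V * cfg.tile_height > P.shape[0]:
                continue
            s = np.array(
                [[direct_simple_ncc(P, D, cfg, u, v) for u in range(3)] for v in range(3)]
            )
            total = (s.sum() - s.min()) / (s.size - 1)
            key = (-total, pu, pv)
            if best is None or key < best[0]:
                best = (key, (pu, pv), total)
    return best[1], best[2]


def direct_simple_ncc(P, D, cfg, u, v):
    rs, cs = cfg.proj_tile_slices(u, v)
    rd, cd = cfg.drr_tile_slices(u, v)
    a = P[rs, cs].ravel()
    b = D[rd, cd].ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / den) if den > 0 else 0.0


class TestMakeTileConfig:
    def test_three_by_three_168px_tiles_cover_a_504px_image(self):
        cfg = make_tile_config((504, 504), U=3, V=3, tile_size=168)
        assert cfg.tile_width == cfg.tile_height == 168
        rs, cs = cfg.proj_tile_slices(2, 2)
        assert rs.stop == 504 and cs.stop == 504  # 9 tiles exactly cover it

    def test_overflowing_offsets_rejected_with_feasible_offset_reported(self):
        with pytest.raises(ValueError, match="maximal feasible"):
            make_tile_config((504, 504), tile_size=168, p_offset=(1, 0))

    def test_recommended_size_within_guidance_band(self):
        size = recommended_tile_size(140)
        assert 1.2 * 140 <= size <= 1.5 * 140

    def test_tile_size_from_tumor_extent_clamped_to_image(self):
        # 1.35 x 140 = 189 would overflow a 504 px image at 3 tiles; the
        # derived size clamps to 168, the guidance band's lower edge
        cfg = make_tile_config((504, 504), tumor_extent_px=140)
        assert cfg.tile_width == 168
        cfg2 = make_tile_config((640, 640), tumor_extent_px=140)
        assert 168 <= cfg2.tile_width <= 210


class TestTileNcc:
    def test_identical_tiles_score_one(self, rng):
        img = rng.random((60, 60))
        cfg = TileConfig(U=3, V=3, tile_width=20, tile_height=20)
        assert tile_ncc(img, img, cfg, 1, 2) == pytest.approx(1.0, abs=1e-12)

    def test_negated_tiles_score_minus_one(self, rng):
        P = rng.random((60, 60))
        D = 5.0 - P
        cfg = TileConfig(U=3, V=3, tile_width=20, tile_height=20)
        assert tile_ncc(P, D, cfg, 0, 0) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        cfg = TileConfig(U=1, V=1, tile_width=8, tile_height=8)
        for _ in range(10):
            P = rng.normal(0, 1, (8, 8))
            D = rng.normal(0, 1, (8, 8))
            assert tile_ncc(P, D, cfg, 0, 0) == pytest.approx(
                direct_ncc_oracle(P, D), abs=1e-12
            )

    def test_constant_tile_scores_zero_by_convention(self, rng):
        P = np.full((20, 20), 7.0)
        D = rng.random((20, 20))
        cfg = TileConfig(U=1, V=1, tile_width=20, tile_height=20)
        assert tile_ncc(P, D, cfg, 0, 0) == 0.0
        assert tile_ncc(D, P, cfg, 0, 0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        gain=st.floats(0.1, 10.0),
        offset=st.floats(-100.0, 100.0),
    )
    def test_bounded_and_invariant_to_positive_affine_maps(self, seed, gain, offset):
        r = np.random.default_rng(seed)
        P = r.normal(0, 1, (12, 12))
        D = r.normal(0, 1, (12, 12))
        cfg = TileConfig(U=1, V=1, tile_width=12, tile_height=12)
        s = tile_ncc(P, D, cfg, 0, 0)
        assert -1.0 <= s <= 1.0
        s2 = tile_ncc(P, gain * D + offset, cfg, 0, 0)
        assert s2 == pytest.approx(s, abs=1e-9)


class TestTotalNcc:
    def test_all_ones_average_to_one(self):
        s = np.ones((3, 3))
        assert total_ncc(s, exclude_bad=True) == 1.0
        assert total_ncc(s, exclude_bad=False) == 1.0

    def test_bad_tile_exclusion_arithmetic(self):
        s = np.full((3, 3), 0.9)
        s[1, 2] = 0.1
        assert total_ncc(s, exclude_bad=True) == pytest.approx(0.9, abs=1e-12)
        assert total_ncc(s, exclude_bad=False) == pytest.approx((8 * 0.9 + 0.1) / 9, abs=1e-12)

    def test_single_tile_with_exclusion_rejected(self):
        with pytest.raises(ValueError):
            total_ncc(np.array([[0.5]]), exclude_bad=True)


class TestFindBadTile:
    def test_clear_minimum(self):
        s = np.ones((3, 3))
        s[2, 1] = 0.2
        assert find_bad_tile(s) == (1, 2)  # (u, v)

    def test_all_equal_ties_to_first_row_major(self):
        assert find_bad_tile(np.ones((3, 3))) == (0, 0)


class TestOptimizeTileShift:
    def test_identical_images_tie_break_to_smallest_offset(self, rng):
        img = rng.random((160, 160))
        base = TileConfig(U=3, V=3, tile_width=40, tile_height=40)
        res = optimize_tile_shift(img, img, base, search_range_px=40, step_px=10)
        assert res.total == pytest.approx(1.0, abs=1e-12)
        assert (res.config.p_u, res.config.p_v) == (0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_scan_on_disc_fixtures(self, seed):
        P, D, base = disc_fixture(seed)
        res = optimize_tile_shift(P, D, base, search_range_px=40, step_px=5)
        (pu, pv), total = brute_force_shift_scan(P, D, base, 40, 5)
        assert (res.config.p_u, res.config.p_v) == (pu, pv)
        assert res.total == pytest.approx(total, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_disc_isolated_into_single_bad_tile(self, seed):
        P, D, base = disc_fixture(seed)
        res = optimize_tile_shift(P, D, base, search_range_px=40, step_px=5)
        s = res.s_matrix
        bu, bv = res.bad_tile
        assert s[bv, bu] < 0.5
        others = np.delete(s.ravel(), bv * 3 + bu)
        assert np.all(others > 0.9)
        # the disc lies entirely within the bad tile
        rs, cs = res.config.proj_tile_slices(bu, bv)
        yy, xx = np.mgrid[0:160, 0:160]
        disc = (yy - 80) ** 2 + (xx - 80) ** 2 <= 16.0**2
        rows, cols = np.nonzero(disc)
        assert rows.min() >= rs.start and rows.max() < rs.stop
        assert cols.min() >= cs.start and cols.max() < cs.stop

    def test_optimized_total_at_least_base_total(self, rng):
        P, D, base = disc_fixture(11)
        res = optimize_tile_shift(P, D, base, search_range_px=40, step_px=5)
        base_s = ncc_matrix(P, D, base)
        assert res.total >= total_ncc(base_s, exclude_bad=True) - 1e-12

    def test_exclusion_after_shift_beats_no_shift_no_exclusion(self):
        P, D, base = disc_fixture(3)
        res = optimize_tile_shift(P, D, base, search_range_px=40, step_px=5)
        plain = total_ncc(ncc_matrix(P, D, base), exclude_bad=False)
        assert res.total > plain

    def test_empty_search_grid_rejected(self, rng):
        img = rng.random((120, 120))
        base = TileConfig(U=3, V=3, tile_width=40, tile_height=40)
        with pytest.raises(ValueError):
            optimize_tile_shift(img, img, base, search_range_px=0, step_px=5)
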