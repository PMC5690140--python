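"""CLAHE and marker detection/removal."""

import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from tiletrack import (
    ClaheParams,
    MarkerSet,
    Volume3D,
    apply_clahe,
    detect_markers,
    remove_markers,
    remove_markers_volume,
)
from tiletrack.preprocess import clahe_region_mappings


def global_equalization_oracle(img, nbins):
    """Direct CDF mapping (plain histogram equalization) for comparison."""
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo)
    bins = np.minimum((norm * nbins).astype(int), nbins - 1)
    hist = np.bincount(bins.ravel(), minlength=nbins)
    cdf = np.cumsum(hist) / img.size
    return cdf[bins]


class TestApplyClahe:
    def test_constant_image_stays_constant_and_idempotent(self):
        img = np.full((40, 40), 3.7)
        out = apply_clahe(img).data
        assert np.ptp(out) == 0.0
        again = apply_clahe(out).data
        assert np.array_equal(out, again)

    def test_output_bounded_in_unit_interval(self, rng):
        img = rng.normal(100, 25, (96, 96))
        out = apply_clahe(img, ClaheParams(grid=(4, 4))).data
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_single_region_infinite_clip_equals_global_equalization(self, rng):
        img = rng.gamma(2.0, 10.0, (64, 64))
        params = ClaheParams(grid=(1, 1), clip_limit=1.0, nbins=256)
        out = apply_clahe(img, params).data
        oracle = global_equalization_oracle(img, 256)
        assert np.max(np.abs(out - oracle)) < 1e-12

    def test_region_histograms_respect_clip_limit_after_redistribution(self, rng):
        img = rng.normal(0, 1, (64, 64)) + np.linspace(0, 4, 64)[None, :]
        params = ClaheParams(grid=(2, 2), clip_limit=0.02, nbins=64)
        mappings, bins, _, _ = clahe_region_mappings(img, params)
        npix = 32 * 32
        limit = max(params.clip_limit * npix, npix / params.nbins)
        for i in range(2):
            for j in range(2):
                region = bins[i * 32 : (i + 1) * 32, j * 32 : (j + 1) * 32]
                hist = np.bincount(region.ravel(), minlength=64).astype(float)
                excess = np.clip(hist - limit, 0, None).sum()
                # mapping increments are the clipped histogram mass
                mass = np.diff(np.concatenate([[0.0], mappings[i, j]])) * npix
                assert np.all(mass <= limit + excess / params.nbins + 1e-9)

    def test_blending_removes_region_boundary_seams(self, rng):
        img = rng.normal(0, 1, (80, 80)).cumsum(axis=1)  # smooth-ish field
        out = apply_clahe(img, ClaheParams(grid=(4, 4))).data
        jumps = np.abs(np.diff(out, axis=1)).max()
        # no discontinuity larger than a modest fraction of the range
        assert jumps < 0.2

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            apply_clahe(np.zeros((0, 5)))


def paste(canvas, patch, r, c):
    canvas[r : r + patch.shape[0], c : c + patch.shape[1]] += patch
    return canvas


def exhaustive_ncc_scan(img, tmpl):
    """Hand-coded exhaustive NCC placement scan (test oracle)."""
    th, tw = tmpl.shape
    dt = tmpl - tmpl.mean()
    nt = np.sqrt((dt * dt).sum())
    best, best_pos = -2.0, (0, 0)
    for r in range(img.shape[0] - th + 1):
        for c in range(img.shape[1] - tw + 1):
            win = img[r : r + th, c : c + tw]
            dw = win - win.mean()
            denom = nt * np.sqrt((dw * dw).sum())
            s = (dw * dt).sum() / denom if denom > 0 else 0.0
            if s > best:
                best, best_pos = s, (r, c)
    return best_pos, best


class TestDetectMarkers:
    def blob(self):
        yy, xx = np.mgrid[-4:5, -4:5]
        return np.sqrt(np.clip(16.0 - yy**2 - xx**2, 0, None))

    def test_single_exact_embedding_found_with_unit_score(self):
        tmpl = self.blob()
        img = paste(np.zeros((60, 60)), tmpl, 17, 23)
        ms = detect_markers(img, tmpl, 1)
        assert ms.centers == [(17 + 4, 23 + 4)]
        assert ms.scores[0] == pytest.approx(1.0, abs=1e-9)

    def test_three_disjoint_copies_all_recovered(self):
        tmpl = self.blob()
        img = np.zeros((80, 80))
        spots = [(5, 8), (40, 50), (65, 20)]
        for r, c in spots:
            paste(img, tmpl, r, c)
        ms = detect_markers(img, tmpl, 3)
        assert sorted(ms.centers) == sorted((r + 4, c + 4) for r, c in spots)

    def test_noisy_copies_match_exhaustive_scan_oracle(self, rng):
        tmpl = self.blob()
        img = paste(np.zeros((50, 50)), tmpl, 21, 13)
        img += rng.normal(0, 0.02 * img.max(), img.shape)
        ms = detect_markers(img, tmpl, 1)
        (r, c), _ = exhaustive_ncc_scan(img, tmpl)
        assert ms.centers[0] == (r + 4, c + 4)
        assert abs(ms.centers[0][0] - 25) <= 1 and abs(ms.centers[0][1] - 17) <= 1

    def test_score_invariant_to_affine_intensity_change(self, rng):
        tmpl = self.blob()
        img = paste(rng.normal(0, 0.1, (50, 50)), tmpl, 10, 30)
        a = detect_markers(img, tmpl, 1)
        b = detect_markers(2.5 * img + 40.0, tmpl, 1)
        assert a.centers == b.centers
        assert a.scores[0] == pytest.approx(b.scores[0], abs=1e-9)

    def test_too_few_peaks_reports_fewer_with_warning(self):
        tmpl = self.blob()
        img = paste(np.zeros((50, 50)), tmpl, 20, 20)
        with pytest.warns(UserWarning):
            ms = detect_markers(img, tmpl, 3, min_score=0.5)
        assert len(ms.centers) == 1

    def test_template_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            detect_markers(np.zeros((5, 5)), np.zeros((9, 9)), 1)


def harmonic_fill_oracle(img, cr, cc, radius):
    """Discrete Laplace solve (4-neighbor) on the disk with image boundary."""
    rows, cols = img.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    inside = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2
    idx = -np.ones(img.shape, dtype=int)
    pts = np.argwhere(inside)
    for k, (r, c) in enumerate(pts):
        idx[r, c] = k
    A = lil_matrix((len(pts), len(pts)))
    b = np.zeros(len(pts))
    for k, (r, c) in enumerate(pts):
        A[k, k] = 4.0
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc2 = r + dr, c + dc
            if inside[rr, cc2]:
                A[k, idx[rr, cc2]] = -1.0
            else:
                b[k] += img[rr, cc2]
    sol = spsolve(A.tocsr(), b)
    out = img.copy()
    out[tuple(pts.T)] = sol
    return out


class TestRemoveMarkers:
    def test_constant_image_is_a_fixed_point(self):
        img = np.full((40, 40), 2.5)
        ms = MarkerSet(centers=[(20, 20)], radius_px=6.0, scores=[1.0])
        out = remove_markers(img, ms).data
        assert np.array_equal(out, img)

    def test_pixels_outside_mask_bit_identical(self, rng):
        img = rng.normal(0, 1, (50, 50))
        ms = MarkerSet(centers=[(25, 25)], radius_px=7.0, scores=[1.0])
        out = remove_markers(img, ms).data
        yy, xx = np.mgrid[0:50, 0:50]
        outside = (yy - 25) ** 2 + (xx - 25) ** 2 > 49.0
        assert np.array_equal(out[outside], img[outside])

    def test_ramp_fill_matches_harmonic_oracle(self):
        yy, xx = np.mgrid[0:40, 0:40]
        img = 2.0 * yy + 0.5 * xx
        ms = MarkerSet(centers=[(20, 20)], radius_px=7.0, scores=[1.0])
        out = remove_markers(img, ms).data
        oracle = harmonic_fill_oracle(img, 20, 20, 7.0)
        inside = (yy - 20) ** 2 + (xx - 20) ** 2 <= 49.0
        span = img[inside].max() - img[inside].min()
        assert np.max(np.abs(out[inside] - oracle[inside])) < 0.02 * span

    def test_fill_stays_within_boundary_ring_range(self, rng):
        img = rng.uniform(5.0, 9.0, (40, 40))
        ms = MarkerSet(centers=[(20, 20)], radius_px=6.0, scores=[1.0])
        out = remove_markers(img, ms).data
        yy, xx = np.mgrid[0:40, 0:40]
        d = np.sqrt((yy - 20) ** 2 + (xx - 20) ** 2)
        inside = d <= 6.0
        ring = (d > 6.0) & (d <= 8.5)
        assert out[inside].min() >= img[ring].min() - 1e-12
        assert out[inside].max() <= img[ring].max() + 1e-12

    def test_disk_touching_border_rejected(self, rng):
        img = rng.normal(0, 1, (30, 30))
        ms = MarkerSet(centers=[(2, 15)], radius_px=5.0, scores=[1.0])
        with pytest.raises(ValueError):
            remove_markers(img, ms)


class TestRemoveMarkersVolume:
    def test_constant_volume_fixed_point_and_locality(self, rng):
        data = rng.normal(10, 1, (24, 24, 24))
        vol = Volume3D(data, (2.0, 2.0, 2.0), (-23.0, -23.0, -23.0))
        out = remove_markers_volume(vol, [(0.0, 0.0, 0.0)], radius_mm=5.0)
        ci = vol.world_to_index(np.zeros(3))
        grids = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        dist = np.sqrt(sum(((g - ci[k]) * 2.0) ** 2 for k, g in enumerate(grids)))
        outside = dist > 5.0
        assert np.array_equal(out.data[outside], vol.data[outside])
        assert not np.array_equal(out.data, vol.data)

        flat = Volume3D(np.full((24, 24, 24), 4.2), (2, 2, 2), (-23, -23, -23))
        out2 = remove_markers_volume(flat, [(0.0, 0.0, 0.0)], radius_mm=5.0)
        assert np.array_equal(out2.data, flat.data)
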