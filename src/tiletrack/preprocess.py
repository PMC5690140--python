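"""Image preprocessing: CLAHE and fiducial-marker removal.

Background DRR values are not linearly related to projection intensities,
so both are contrast-corrected with contrast-limited adaptive histogram
equalization (CLAHE) before tile matching. Implanted radio-opaque markers
(used only as an independent position reference) are detected by template
matching and removed by a shrinking-radius inpainting that repeatedly
replaces the current boundary ring of the marker disk with the mean of its
already-valid neighbors, so the hole fills smoothly from the outside in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, gaussian_filter
from skimage.feature import match_template as _sk_match_template

from .drr import Volume3D
from .geometry import ProjectionGeometry, project_point
from .images import Image2D, as_image_array

__all__ = [
    "ClaheParams",
    "MarkerSet",
    "MarkerConstellation",
    "apply_clahe",
    "clahe_region_mappings",
    "detect_markers",
    "remove_markers",
    "remove_markers_volume",
    "build_marker_constellation",
    "locate_constellation",
]


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE configuration.

    ``clip_limit`` is the histogram clip expressed as a fraction of the
    region pixel count (the adapthisteq convention; 0.01 over a 168² tile
    with 256 bins is ≈2.6× the uniform bin height). The effective count
    limit is floored at the uniform bin height so excess redistribution
    always converges; a clip limit of 1.0 disables clipping entirely and
    reduces each region to plain histogram equalization.
    """

    grid: tuple[int, int] = (8, 8)  # (rows, cols) of contextual regions
    clip_limit: float = 0.01
    nbins: int = 256

    def __post_init__(self) -> None:
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("region grid must be at least 1x1")
        if self.clip_limit <= 0:
            raise ValueError("clip limit must be positive")
        if self.nbins < 2:
            raise ValueError("need at least 2 histogram bins")


def _region_edges(n: int, parts: int) -> np.ndarray:
    return np.round(np.linspace(0, n, parts + 1)).astype(int)


def clahe_region_mappings(image, params: ClaheParams):
    """Per-region clipped-and-redistributed equalization mappings.

    Returns (mappings, bin_index, row_centers, col_centers) where
    ``mappings[i, j]`` maps a bin index to an output gray level in [0, 1].
    Exposed separately so the clip-limit contract is testable.
    """
    img = as_image_array(image)
    if img.size == 0:
        raise ValueError("cannot equalize an empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        norm = (img - lo) / (hi - lo)
    else:
        norm = np.zeros_like(img)
    bins = np.minimum((norm * params.nbins).astype(int), params.nbins - 1)

    rows, cols = img.shape
    re = _region_edges(rows, params.grid[0])
    ce = _region_edges(cols, params.grid[1])
    mappings = np.zeros((params.grid[0], params.grid[1], params.nbins))
    for i in range(params.grid[0]):
        for j in range(params.grid[1]):
            region = bins[re[i] : re[i + 1], ce[j] : ce[j + 1]]
            npix = region.size
            if npix == 0:
                raise ValueError("degenerate (zero-size) contextual region")
            hist = np.bincount(region.ravel(), minlength=params.nbins).astype(float)
            uniform = npix / params.nbins
            limit = max(params.clip_limit * npix, uniform)
            excess = np.clip(hist - limit, 0.0, None).sum()
            hist = np.minimum(hist, limit) + excess / params.nbins
            cdf = np.cumsum(hist)
            mappings[i, j] = cdf / cdf[-1]
    row_centers = (re[:-1] + re[1:] - 1) / 2.0
    col_centers = (ce[:-1] + ce[1:] - 1) / 2.0
    return mappings, bins, row_centers, col_centers


def _interp_weights(coords: np.ndarray, centers: np.ndarray):
    """Clamped linear interpolation indices/weights along one axis."""
    if centers.size == 1:
        i0 = np.zeros(coords.size, dtype=int)
        return i0, i0, np.ones(coords.size)
    idx = np.searchsorted(centers, coords) - 1
    idx = np.clip(idx, 0, centers.size - 2)
    denom = centers[idx + 1] - centers[idx]
    w1 = np.clip((coords - centers[idx]) / denom, 0.0, 1.0)
    return idx, idx + 1, w1


def apply_clahe(image, params: ClaheParams | None = None) -> Image2D:
    """Contrast-limited adaptive histogram equalization, output in [0, 1].

    Each contextual region gets a clipped histogram (excess counts
    redistributed equally over all bins) and the resulting CDF mapping;
    pixel values are bilinearly blended between the four nearest region
    mappings, with clamping outside the outermost region centers, which
    removes region-boundary seams.
    """
    params = params or ClaheParams()
    pitch = image.pixel_pitch_mm if isinstance(image, Image2D) else 1.0
    kind = image.kind if isinstance(image, Image2D) else "projection"
    mappings, bins, rc, cc = clahe_region_mappings(image, params)
    rows, cols = bins.shape
    if np.ptp(as_image_array(image)) == 0.0:
        # exactly constant input: every region maps bin 0 identically, so
        # skip blending and return an exactly constant (idempotent) output
        return Image2D(
            np.full((rows, cols), mappings[0, 0, 0]), pixel_pitch_mm=pitch, kind=kind
        )

    i0, i1, wy = _interp_weights(np.arange(rows, dtype=float), rc)
    j0, j1, wx = _interp_weights(np.arange(cols, dtype=float), cc)
    WY = wy[:, None]
    WX = wx[None, :]
    out = (
        (1 - WY) * (1 - WX) * mappings[i0[:, None], j0[None, :], bins]
        + (1 - WY) * WX * mappings[i0[:, None], j1[None, :], bins]
        + WY * (1 - WX) * mappings[i1[:, None], j0[None, :], bins]
        + WY * WX * mappings[i1[:, None], j1[None, :], bins]
    )
    return Image2D(out, pixel_pitch_mm=pitch, kind=kind)


@dataclass
class MarkerSet:
    """Detected marker disks: centers (row, col) px, common radius, scores."""

    centers: list[tuple[int, int]]
    radius_px: float
    scores: list[float]

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("marker radius must be positive")


def detect_markers(
    image,
    marker_template,
    count: int,
    min_score: float = 0.2,
    region: tuple[int, int, int, int] | None = None,
    min_separation_px: int | None = None,
) -> MarkerSet:
    """Find the ``count`` best non-overlapping template matches.

    NCC of the template is evaluated at every placement (FFT-based); peaks
    are taken greedily, suppressing a ``min_separation_px`` neighborhood
    (default: the template footprint, so detections cannot overlap; pass a
    smaller value to resolve adjacent markers) around each accepted peak.
    ``region`` restricts the search to (row0, row1, col0, col1) of the
    image. If fewer than ``count`` peaks survive, the shorter list is
    returned with a warning.
    """
    img = as_image_array(image)
    tmpl = np.asarray(marker_template, dtype=float)
    if tmpl.shape[0] >= img.shape[0] or tmpl.shape[1] >= img.shape[1]:
        raise ValueError("template must be smaller than the image")
    th, tw = tmpl.shape
    ncc = _sk_match_template(img, tmpl, pad_input=False).copy()
    if region is not None:
        r0, r1, c0, c1 = region
        masked = np.full_like(ncc, -np.inf)
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1 = min(r1 - th + 1, ncc.shape[0])
        cc1 = min(c1 - tw + 1, ncc.shape[1])
        if rr1 > rr0 and cc1 > cc0:
            masked[rr0:rr1, cc0:cc1] = ncc[rr0:rr1, cc0:cc1]
        ncc = masked
    sep = max(th, tw) - 1 if min_separation_px is None else int(min_separation_px)
    centers: list[tuple[int, int]] = []
    scores: list[float] = []
    for _ in range(count):
        peak = np.unravel_index(np.argmax(ncc), ncc.shape)
        score = float(ncc[peak])
        if not np.isfinite(score) or score < min_score:
            break
        r, c = int(peak[0]), int(peak[1])
        centers.append((r + th // 2, c + tw // 2))
        scores.append(score)
        ncc[max(r - sep, 0) : r + sep + 1, max(c - sep, 0) : c + sep + 1] = -np.inf
    if len(centers) < count:
        warnings.warn(
            f"requested {count} markers but only {len(centers)} non-overlapping "
            "peaks were found",
            stacklevel=2,
        )
    return MarkerSet(centers=centers, radius_px=max(th, tw) / 2.0, scores=scores)


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    offs = np.indices((3,) * ndim).reshape(ndim, -1).T - 1
    return [tuple(o) for o in offs if any(o)]


def _peel_fill(data: np.ndarray, unknown: np.ndarray, dist: np.ndarray) -> None:
    """Seed ``unknown`` voxels in place, outermost (by ``dist``) first.

    Within each peel, pixels are visited in a fixed raster order and each
    is replaced by the mean of its already-valid 8- (2D) or 26- (3D)
    neighbors; freshly filled pixels immediately count as valid, which
    makes the result deterministic.
    """
    offsets = _neighbor_offsets(data.ndim)
    coords = np.array(np.nonzero(unknown)).T
    d = dist[tuple(coords.T)]
    # Raster order = lexicographic coordinate order within equal distance.
    order = np.lexsort(tuple(coords.T[::-1]) + (-d,))
    valid = ~unknown
    shape = data.shape
    for ci in order:
        c = coords[ci]
        acc = 0.0
        n = 0
        for off in offsets:
            q = c + off
            if np.any(q < 0) or np.any(q >= shape):
                continue
            qt = tuple(q)
            if valid[qt]:
                acc += data[qt]
                n += 1
        if n == 0:
            raise RuntimeError("inpainting pixel has no valid neighbor")
        data[tuple(c)] = acc / n
        valid[tuple(c)] = True


def _relax_fill(
    data: np.ndarray, unknown: np.ndarray, tol: float = 1e-10, max_iter: int = 2000
) -> None:
    """Iterate full-neighborhood averaging over the seeded fill in place.

    The outward-in peel alone biases the fill toward the first-processed
    boundary side; repeating the neighbor averaging (Jacobi sweeps over
    all unknown pixels at once) converges to the fill where every filled
    pixel equals the mean of its full 8- (2D) or 26- (3D) neighborhood —
    the discretely harmonic interpolant of the surrounding intensities,
    i.e. the smooth hole fill. Unknown pixels must not touch the array
    border (callers pad by one pixel).
    """
    kernel = np.ones((3,) * data.ndim)
    kernel[(1,) * data.ndim] = 0.0
    n_neighbors = kernel.sum()
    known = ~unknown
    scale = float(np.abs(data[known]).max()) if known.any() else 0.0
    if scale == 0.0:
        scale = 1.0
    for _ in range(max_iter):
        nb = convolve(data, kernel, mode="constant", cval=0.0)
        new = nb[unknown] / n_neighbors
        delta = np.abs(new - data[unknown]).max() if new.size else 0.0
        data[unknown] = new
        if delta <= tol * scale:
            break


def _fill_region(patch: np.ndarray, unknown: np.ndarray, dist: np.ndarray) -> None:
    """Inpaint ``unknown`` within ``patch``: shift to a reference, peel,
    relax, write back only the filled pixels.

    The reference shift makes a constant patch an exact fixed point (the
    shifted field is exactly zero, which every averaging step preserves
    bit-for-bit) and keeps pixels outside the region bit-identical.
    """
    known_idx = np.nonzero(~unknown)
    if len(known_idx[0]) == 0:
        raise ValueError("no valid pixels around the inpainting region")
    ref = patch[tuple(k[0] for k in known_idx)]
    work = patch - ref
    _peel_fill(work, unknown, dist)
    _relax_fill(work, unknown)
    patch[unknown] = work[unknown] + ref


def remove_markers(image, markers: MarkerSet) -> Image2D:
    """Inpaint marker disks by iterative shrinking-radius averaging.

    Pixels outside the disks are returned bit-identical; inside, values
    are seeded boundary-ring first (every fill a convex combination of
    surrounding existing intensities) and the neighbor averaging is then
    repeated until the fill is the smooth, discretely harmonic
    interpolant of the surrounding pixels. Overlapping disks are filled
    as one region (distance to the nearest center orders the peeling).
    Disks touching the image border are rejected.
    """
    img = as_image_array(image).copy()
    pitch = image.pixel_pitch_mm if isinstance(image, Image2D) else 1.0
    kind = image.kind if isinstance(image, Image2D) else "projection"
    rows, cols = img.shape
    r = markers.radius_px
    if not markers.centers:
        return Image2D(img, pixel_pitch_mm=pitch, kind=kind)
    for cr, cc in markers.centers:
        if cr - r < 1 or cc - r < 1 or cr + r > rows - 2 or cc + r > cols - 2:
            raise ValueError("marker disk touches the image border")
    lo_r = int(np.floor(min(cr for cr, _ in markers.centers) - r)) - 1
    hi_r = int(np.ceil(max(cr for cr, _ in markers.centers) + r)) + 2
    lo_c = int(np.floor(min(cc for _, cc in markers.centers) - r)) - 1
    hi_c = int(np.ceil(max(cc for _, cc in markers.centers) + r)) + 2
    lo_r, lo_c = max(lo_r, 0), max(lo_c, 0)
    hi_r, hi_c = min(hi_r, rows), min(hi_c, cols)
    patch = img[lo_r:hi_r, lo_c:hi_c]
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dist = np.full(patch.shape, np.inf)
    for cr, cc in markers.centers:
        dist = np.minimum(dist, np.sqrt((yy - cr) ** 2 + (xx - cc) ** 2))
    unknown = dist <= r
    if unknown.any():
        _fill_region(patch, unknown, dist)
    return Image2D(img, pixel_pitch_mm=pitch, kind=kind)


@dataclass
class MarkerConstellation:
    """The implanted markers as one rigid detector-plane pattern.

    Markers are implanted next to the tumor and move with it, so their
    projected layout relative to the tumor center is (to within the small
    magnification change over the motion range) fixed per imaging angle.
    Matching all markers jointly as a single composite template is far
    more discriminative than hunting individual small blobs among rib and
    chest-wall edges, and anchoring the search window to the current tumor
    estimate removes the remaining false peaks.
    """

    template: np.ndarray
    blob_offsets: list[tuple[float, float]]  # (row, col) of each blob in the template
    anchor_offset: tuple[float, float]  # template top-left minus tumor-center px (row, col)
    highpass_sigma: float
    inpaint_radius_px: float
    search_halfwidth_px: int = 14


def build_marker_constellation(
    geometry: ProjectionGeometry,
    marker_centers_mm,
    tumor_center_mm,
    marker_diameter_mm: float = 5.5,
    blur_px: float = 1.2,
    inpaint_margin_px: float = 2.0,
) -> MarkerConstellation:
    """Project the planning-CT marker centers into a composite template.

    Each marker contributes its sphere chord-length profile (the ideal
    attenuation integral), lightly blurred to the voxel footprint of the
    rasterized volume. The template records where it sits relative to the
    projected tumor center, so a tumor-position prior predicts the
    constellation's location.
    """
    r_px = (
        marker_diameter_mm / 2.0 * geometry.magnification / geometry.pixel_pitch_mm
    )
    pps = [project_point(geometry, c) for c in marker_centers_mm]
    vs = np.array([p.v_px for p in pps])
    us = np.array([p.u_px for p in pps])
    margin = int(np.ceil(r_px)) + 2
    height = int(np.ceil(vs.max() - vs.min())) + 2 * margin + 1
    width = int(np.ceil(us.max() - us.min())) + 2 * margin + 1
    yy, xx = np.mgrid[0:height, 0:width]
    template = np.zeros((height, width))
    offsets = []
    for v, u in zip(vs, us):
        dv = v - vs.min() + margin
        du = u - us.min() + margin
        offsets.append((float(dv), float(du)))
        template += 2.0 * np.sqrt(
            np.clip(r_px**2 - (yy - dv) ** 2 - (xx - du) ** 2, 0.0, None)
        )
    tc = project_point(geometry, tumor_center_mm)
    return MarkerConstellation(
        template=gaussian_filter(template, blur_px),
        blob_offsets=offsets,
        anchor_offset=(
            float(vs.min() - margin - tc.v_px),
            float(us.min() - margin - tc.u_px),
        ),
        highpass_sigma=2.0 * r_px,
        inpaint_radius_px=r_px + inpaint_margin_px,
    )


def locate_constellation(
    image, constellation: MarkerConstellation, tumor_center_px: tuple[float, float]
) -> MarkerSet:
    """Find the marker constellation near a tumor-center estimate.

    The image is high-pass filtered (markers are small-scale; smooth
    anatomy is flattened), the composite template is matched by NCC in a
    window around its position predicted from ``tumor_center_px`` (row,
    col), and the per-marker centers are read off the best placement.
    """
    img = as_image_array(image)
    hp = img - gaussian_filter(img, constellation.highpass_sigma)
    tmpl = constellation.template
    pr = int(round(tumor_center_px[0] + constellation.anchor_offset[0]))
    pc = int(round(tumor_center_px[1] + constellation.anchor_offset[1]))
    w = constellation.search_halfwidth_px
    r0 = max(pr - w, 0)
    c0 = max(pc - w, 0)
    r1 = min(pr + tmpl.shape[0] + w, img.shape[0])
    c1 = min(pc + tmpl.shape[1] + w, img.shape[1])
    if r1 - r0 <= tmpl.shape[0] or c1 - c0 <= tmpl.shape[1]:
        raise ValueError("constellation search window falls outside the image")
    ncc = _sk_match_template(hp[r0:r1, c0:c1], tmpl, pad_input=False)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    score = float(ncc[peak])
    centers = [
        (int(round(peak[0] + r0 + dv)), int(round(peak[1] + c0 + du)))
        for dv, du in constellation.blob_offsets
    ]
    return MarkerSet(
        centers=centers,
        radius_px=constellation.inpaint_radius_px,
        scores=[score] * len(centers),
    )


def remove_markers_volume(
    volume: Volume3D, centers_mm, radius_mm: float
) -> Volume3D:
    """Remove marker spheres from a CT volume by the same peel algorithm.

    Spheres around ``centers_mm`` (world millimetres, radius ``radius_mm``)
    are filled outermost-shell first from the mean of already-valid
    26-neighbors. Used on the planning CT before DRR generation so that
    background DRRs are marker-free.
    """
    out = volume.copy()
    for center in centers_mm:
        ci = out.world_to_index(np.asarray(center, dtype=float))
        r_vox = radius_mm / volume.spacing  # per-axis radius in voxels
        lo = np.maximum(np.floor(ci - r_vox).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(ci + r_vox).astype(int) + 2, np.array(out.shape))
        if np.any(lo < 1) or np.any(hi > np.array(out.shape) - 1):
            raise ValueError("marker sphere touches the volume border")
        patch = out.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        grids = np.meshgrid(
            *[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij"
        )
        # physical distance accounts for anisotropic voxels
        dist = np.sqrt(
            sum(((g - ci[k]) * volume.spacing[k]) ** 2 for k, g in enumerate(grids))
        )
        unknown = dist <= radius_mm
        if unknown.any():
            _fill_region(patch, unknown, dist)
    return out
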