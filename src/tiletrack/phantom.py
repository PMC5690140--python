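"""Synthetic respiratory torso phantom with known ground truth.

The digital phantom emulates the physical torso phantom used to validate
markerless tumor tracking: an elliptical soft-tissue body with two lung
ellipsoids, elliptical bony rib rings, a water-density heart sphere, a
cylindrical ~3 cm tumor inside one lung, and implanted 5.5 mm spherical
fiducial markers next to the tumor. All shapes are analytic primitives
rasterized at voxel centers, so the ground truth (tumor center, marker
centers, structure volumes) is exact.

Tumor motion is simulated by shifting the masked tumor (plus markers)
subvolume with trilinear resampling and compositing it over a lung-filled
background — the same background/tumor separation the tracking method
itself uses. Simulated kV projections are DRRs of the composed volume with
a controllable projection-vs-DRR discrepancy applied on top: a monotone
gamma intensity map, a low-frequency multiplicative bias field, and
additive Gaussian noise, standing in for the orientation/scatter/noise
mismatch seen between real projections and DRRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .drr import Volume3D, compute_drr, crop_to_support, split_volume
from .geometry import ProjectionGeometry, ProjectedPoint, project_point
from .images import Image2D

__all__ = [
    "TissueDensities",
    "PhantomSpec",
    "MotionPattern",
    "DistortionSpec",
    "GroundTruthRecord",
    "build_torso_volume",
    "moving_region_mask",
    "sample_trajectory",
    "apply_distortion",
    "simulate_kv_projection",
    "KvSimulator",
    "marker_projection_template",
]


@dataclass(frozen=True)
class TissueDensities:
    """Unitless per-mm attenuation values; only the ordering matters."""

    air: float = 0.0
    body: float = 1.0
    lung: float = 0.2
    bone: float = 1.8
    water: float = 1.0
    tumor: float = 1.1
    marker: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital torso (all lengths in millimetres).

    The default tumor is a 30 mm diameter × 30 mm height cylinder (axis
    superior-inferior) centered in the right lung, with three 5.5 mm
    markers implanted around it. Axial voxel spacing defaults to the 3 mm
    CT slice thickness.
    """

    body_semiaxes: tuple[float, float, float] = (140.0, 95.0, 115.0)
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-55.0, -5.0, 15.0),
        (55.0, -5.0, 15.0),
    )
    lung_semiaxes: tuple[float, float, float] = (45.0, 55.0, 72.0)
    rib_count: int = 8
    rib_ring_semiaxes: tuple[float, float] = (125.0, 82.0)
    rib_band_fraction: float = 0.10  # radial band thickness as fraction of the ring
    rib_half_height_mm: float = 4.0
    rib_spacing_mm: float = 24.0
    rib_center_z_mm: float = 15.0
    heart_center: tuple[float, float, float] = (10.0, 20.0, 0.0)
    heart_radius_mm: float = 35.0
    tumor_center: tuple[float, float, float] = (55.0, -5.0, 5.0)
    tumor_diameter_mm: float = 30.0
    tumor_height_mm: float = 30.0
    marker_diameter_mm: float = 5.5
    marker_offsets: tuple[tuple[float, float, float], ...] = (
        (20.0, 0.0, 6.0),
        (-16.0, 12.0, -6.0),
        (0.0, -16.0, 11.0),
    )
    densities: TissueDensities = field(default_factory=TissueDensities)
    spacing: tuple[float, float, float] = (2.5, 2.5, 3.0)
    margin_mm: float = 6.0

    def __post_init__(self) -> None:
        for name in ("body_semiaxes", "lung_semiaxes", "spacing"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if self.tumor_diameter_mm <= 0 or self.tumor_height_mm <= 0:
            raise ValueError("tumor dimensions must be strictly positive")
        if self.marker_diameter_mm <= 0:
            raise ValueError("marker diameter must be strictly positive")
        if not self._tumor_inside_a_lung():
            raise ValueError("tumor cylinder is not fully inside a lung ellipsoid")
        self._check_markers_disjoint()

    def _tumor_inside_a_lung(self, displacement=(0.0, 0.0, 0.0)) -> bool:
        c = np.asarray(self.tumor_center) + np.asarray(displacement)
        r = self.tumor_diameter_mm / 2.0
        h = self.tumor_height_mm / 2.0
        phis = np.linspace(0.0, 2 * math.pi, 48, endpoint=False)
        rim = np.stack([r * np.cos(phis), r * np.sin(phis), np.zeros_like(phis)], axis=1)
        pts = np.concatenate([rim + [0, 0, h], rim + [0, 0, -h]]) + c
        for lc in self.lung_centers:
            q = (pts - np.asarray(lc)) / np.asarray(self.lung_semiaxes)
            if np.all((q**2).sum(axis=1) <= 1.0):
                return True
        return False

    def _check_markers_disjoint(self) -> None:
        centers = [np.asarray(self.tumor_center) + np.asarray(o) for o in self.marker_offsets]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < self.marker_diameter_mm:
                    raise ValueError("marker spheres overlap")

    def marker_centers(self) -> list[np.ndarray]:
        return [np.asarray(self.tumor_center) + np.asarray(o) for o in self.marker_offsets]


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    half = np.asarray(spec.body_semiaxes) + spec.margin_mm
    sp = np.asarray(spec.spacing)
    n = 2 * np.ceil(half / sp).astype(int) + 1
    origin = -(n - 1) / 2.0 * sp
    xs = origin[0] + np.arange(n[0]) * sp[0]
    ys = origin[1] + np.arange(n[1]) * sp[1]
    zs = origin[2] + np.arange(n[2]) * sp[2]
    return origin, sp, xs[:, None, None], ys[None, :, None], zs[None, None, :]


def _tumor_mask_array(spec: PhantomSpec, x, y, z) -> np.ndarray:
    cx, cy, cz = spec.tumor_center
    r = spec.tumor_diameter_mm / 2.0
    h = spec.tumor_height_mm / 2.0
    return ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (np.abs(z - cz) <= h)


def build_torso_volume(
    spec: PhantomSpec,
) -> tuple[Volume3D, Volume3D, list[np.ndarray]]:
    """Rasterize the torso phantom.

    Returns the attenuation volume, a binary tumor-contour mask on the same
    grid, and the marker centers in world millimetres. Structures are
    painted in order air → body → lungs → heart → ribs → tumor → markers,
    each overwriting the previous, so overlaps resolve deterministically.
    """
    origin, sp, x, y, z = _grid(spec)
    d = spec.densities
    shape = np.broadcast_shapes(x.shape, y.shape, z.shape)
    vol = np.full(shape, d.air, dtype=float)

    ba = np.asarray(spec.body_semiaxes)
    body = (x / ba[0]) ** 2 + (y / ba[1]) ** 2 + (z / ba[2]) ** 2 <= 1.0
    vol[body] = d.body

    la = np.asarray(spec.lung_semiaxes)
    for lc in spec.lung_centers:
        lung = ((x - lc[0]) / la[0]) ** 2 + ((y - lc[1]) / la[1]) ** 2 + (
            (z - lc[2]) / la[2]
        ) ** 2 <= 1.0
        vol[lung] = d.lung

    hc = spec.heart_center
    heart = (x - hc[0]) ** 2 + (y - hc[1]) ** 2 + (z - hc[2]) ** 2 <= spec.heart_radius_mm**2
    vol[heart] = d.water

    if spec.rib_count > 0:
        ra, rb = spec.rib_ring_semiaxes
        e = np.sqrt((x / ra) ** 2 + (y / rb) ** 2)
        band = (e >= 1.0 - spec.rib_band_fraction) & (e <= 1.0)
        z0 = spec.rib_center_z_mm
        for i in range(spec.rib_count):
            zi = z0 + (i - (spec.rib_count - 1) / 2.0) * spec.rib_spacing_mm
            rib = band & (np.abs(z - zi) <= spec.rib_half_height_mm) & body
            vol[rib] = d.bone

    tumor = _tumor_mask_array(spec, x, y, z)
    vol[tumor] = d.tumor

    centers = spec.marker_centers()
    rm = spec.marker_diameter_mm / 2.0
    for c in centers:
        m = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= rm**2
        vol[m] = d.marker

    ct = Volume3D(vol, sp, origin)
    mask = Volume3D(tumor.astype(float), sp, origin)
    return ct, mask, centers


def moving_region_mask(spec: PhantomSpec, like: Volume3D) -> Volume3D:
    """Binary mask of the moving unit: tumor cylinder plus marker spheres.

    The markers are implanted next to the tumor and ride the same motion
    platform, so the simulator shifts them together with the tumor.
    """
    origin, sp, x, y, z = _grid(spec)
    m = _tumor_mask_array(spec, x, y, z)
    rm = spec.marker_diameter_mm / 2.0 + max(spec.spacing)  # pad for partial volume
    for c in spec.marker_centers():
        m |= (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= rm**2
    out = Volume3D(m.astype(float), sp, origin)
    if out.shape != like.shape:
        raise ValueError("mask grid does not match the volume grid")
    return out


@dataclass(frozen=True)
class MotionPattern:
    """Programmable respiratory displacement pattern.

    ``amplitude_mm`` is the per-axis peak displacement. ``sinusoid`` gives
    A·sin(2πt/T + φ); ``cos4`` gives A·cos⁴(πt/T + φ), the flattened
    end-exhale waveform commonly used for breathing; ``piecewise-table``
    linearly interpolates a user table (cyclically).
    """

    name: str = "sinusoid"
    amplitude_mm: tuple[float, float, float] = (0.0, 0.0, 10.0)
    period_s: float = 4.0
    phase_rad: float = 0.0
    frame_rate_hz: float = 5.0
    n_frames: int = 20
    table: tuple[tuple[float, ...], tuple[tuple[float, float, float], ...]] | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitude_mm):
            raise ValueError("amplitude must be non-negative")
        if self.period_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("period and frame rate must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def sample_trajectory(pattern: MotionPattern, frame_index: int) -> np.ndarray:
    """Deterministic 3D displacement (mm) of the tumor at a frame."""
    if not 0 <= frame_index < pattern.n_frames:
        raise ValueError("frame index out of range")
    t = frame_index / pattern.frame_rate_hz
    amp = np.asarray(pattern.amplitude_mm, dtype=float)
    if pattern.name == "sinusoid":
        return amp * math.sin(2 * math.pi * t / pattern.period_s + pattern.phase_rad)
    if pattern.name == "cos4":
        return amp * math.cos(math.pi * t / pattern.period_s + pattern.phase_rad) ** 4
    if pattern.name == "piecewise-table":
        if pattern.table is None:
            raise ValueError("piecewise-table pattern requires a table")
        times = np.asarray(pattern.table[0], dtype=float)
        disps = np.asarray(pattern.table[1], dtype=float)
        tt = t % times[-1] if times[-1] > 0 else 0.0
        return np.array([np.interp(tt, times, disps[:, k]) for k in range(3)])
    raise ValueError(f"unknown motion pattern {pattern.name!r}")


@dataclass(frozen=True)
class DistortionSpec:
    """Controllable projection-vs-DRR discrepancy model.

    Applied in order: monotone gamma map on the max-normalized image, then
    a multiplicative low-frequency bias field of relative amplitude
    ``bias_amplitude`` and spatial scale ``bias_scale_px``, then additive
    Gaussian noise with SD ``noise_sd`` × the image dynamic range. Each
    part switches off at its neutral value. Bit-reproducible given seed.
    """

    gamma: float = 1.3
    bias_amplitude: float = 0.10
    bias_scale_px: float = 64.0
    noise_sd: float = 0.02
    seed: int | Sequence[int] = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.bias_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("bias amplitude and noise SD must be non-negative")
        if self.bias_scale_px <= 0:
            raise ValueError("bias spatial scale must be positive")


def apply_distortion(image: Image2D, spec: DistortionSpec) -> Image2D:
    """Apply the gamma → bias-field → noise discrepancy model."""
    rng = np.random.default_rng(spec.seed)
    data = np.asarray(image.data, dtype=float)
    peak = data.max()
    x = data / peak if peak > 0 else data.copy()
    y = np.power(np.clip(x, 0.0, None), spec.gamma)
    if spec.bias_amplitude > 0:
        coarse_shape = tuple(
            max(int(np.ceil(s / spec.bias_scale_px)) + 1, 2) for s in data.shape
        )
        coarse = rng.standard_normal(coarse_shape)
        zoom = [s / c for s, c in zip(data.shape, coarse_shape)]
        bias = ndimage.zoom(coarse, zoom, order=3, grid_mode=True, mode="nearest")
        bias = bias[: data.shape[0], : data.shape[1]]
        bias /= max(np.abs(bias).max(), 1e-12)
        y = y * (1.0 + spec.bias_amplitude * bias)
    if spec.noise_sd > 0:
        dyn = y.max() - y.min()
        y = y + rng.normal(0.0, spec.noise_sd * dyn, size=y.shape)
    return Image2D(y, pixel_pitch_mm=image.pixel_pitch_mm, kind="projection")


class GroundTruthRecord(NamedTuple):
    """True detector-plane position of the displaced tumor center."""

    u_px: float
    v_px: float
    x_mm_iso: float
    y_mm_iso: float


def _truth(geometry: ProjectionGeometry, center_mm) -> GroundTruthRecord:
    pp: ProjectedPoint = project_point(geometry, center_mm)
    inv_mag = geometry.sad_mm / geometry.sdd_mm
    return GroundTruthRecord(pp.u_px, pp.v_px, pp.u_mm * inv_mag, pp.v_mm * inv_mag)


def _shift_volume(excess: np.ndarray, displacement_mm, spacing) -> np.ndarray:
    shift_vox = np.asarray(displacement_mm, dtype=float) / np.asarray(spacing)
    return ndimage.shift(excess, shift_vox, order=1, mode="constant", cval=0.0)


def simulate_kv_projection(
    ct: Volume3D,
    tumor_mask: Volume3D,
    geometry: ProjectionGeometry,
    displacement_mm=(0.0, 0.0, 0.0),
    distortion: DistortionSpec | None = None,
    moving_mask: Volume3D | None = None,
    tumor_center_mm=(0.0, 0.0, 0.0),
) -> tuple[Image2D, GroundTruthRecord]:
    """Simulate one kV projection frame with known ground truth.

    The frame volume is the background (CT with the moving region excised
    and shell-filled) plus the moving region's excess attenuation shifted
    by ``displacement_mm`` with trilinear resampling. Zero displacement
    reproduces the unmodified CT exactly, so the undistorted projection is
    bit-identical to the CT's DRR. The truth record is the perspective
    projection of the displaced tumor center.
    """
    _mask = moving_mask if moving_mask is not None else tumor_mask
    if _mask.shape != ct.shape:
        raise ValueError("mask grid does not match the CT grid")
    disp = np.asarray(displacement_mm, dtype=float)
    if np.all(disp == 0.0):
        frame_vol = ct
    else:
        background, _ = split_volume(ct, _mask, fill_mode="shell-mean")
        m = _mask.data > 0.5
        excess = np.where(m, ct.data - background.data, 0.0)
        # Reject displacements pushing the moving region out of the grid.
        idx = np.array(np.nonzero(m), dtype=float)
        lo_idx = idx.min(axis=1) + disp / ct.spacing
        hi_idx = idx.max(axis=1) + disp / ct.spacing
        if np.any(lo_idx < 1) or np.any(hi_idx > np.array(ct.shape) - 2):
            raise ValueError("displacement moves the tumor outside the volume")
        frame_vol = Volume3D(
            background.data + _shift_volume(excess, disp, ct.spacing),
            ct.spacing,
            ct.origin,
        )
    proj = compute_drr(frame_vol, geometry, kind="projection")
    if distortion is not None:
        proj = apply_distortion(proj, distortion)
    truth = _truth(geometry, np.asarray(tumor_center_mm, dtype=float) + disp)
    return proj, truth


class KvSimulator:
    """Fast multi-frame projection simulator.

    Precomputes the static background DRR per imaging angle and ray-traces
    only the (cropped) moving excess subvolume per frame; by linearity of
    the attenuation integral the sum equals the composed-volume DRR to
    numerical tolerance. Intended for long multi-angle experiments where
    re-tracing the full torso for every frame would dominate the runtime.
    """

    def __init__(
        self,
        ct: Volume3D,
        moving_mask: Volume3D,
        tumor_center_mm,
        base_geometry: ProjectionGeometry,
        max_displacement_mm: float = 30.0,
    ) -> None:
        self.base_geometry = base_geometry
        self.tumor_center = np.asarray(tumor_center_mm, dtype=float)
        background, _ = split_volume(ct, moving_mask, fill_mode="shell-mean")
        m = moving_mask.data > 0.5
        excess = np.where(m, ct.data - background.data, 0.0)
        self.background = background
        pad = int(np.ceil(max_displacement_mm / min(ct.spacing))) + 2
        full = Volume3D(excess, ct.spacing, ct.origin)
        cropped = crop_to_support(full, margin_voxels=1)
        padded = np.pad(cropped.data, pad)
        origin = cropped.origin - pad * cropped.spacing
        self.excess = Volume3D(padded, cropped.spacing, origin)
        self._bg_cache: dict[float, Image2D] = {}

    def _geom(self, gantry_deg: float, imager_deg: float) -> ProjectionGeometry:
        return self.base_geometry.with_angles(gantry_deg, imager_deg)

    def background_drr(self, gantry_deg: float, imager_deg: float) -> Image2D:
        angle = round((gantry_deg + imager_deg) % 360.0, 6)
        if angle not in self._bg_cache:
            self._bg_cache[angle] = compute_drr(
                self.background, self._geom(gantry_deg, imager_deg)
            )
        return self._bg_cache[angle]

    def frame(
        self,
        gantry_deg: float,
        imager_deg: float,
        displacement_mm,
        distortion: DistortionSpec | None = None,
    ) -> tuple[Image2D, GroundTruthRecord]:
        disp = np.asarray(displacement_mm, dtype=float)
        geom = self._geom(gantry_deg, imager_deg)
        shifted = Volume3D(
            _shift_volume(self.excess.data, disp, self.excess.spacing),
            self.excess.spacing,
            self.excess.origin,
        )
        moving = compute_drr(shifted, geom, kind="projection")
        bg = self.background_drr(gantry_deg, imager_deg)
        proj = Image2D(bg.data + moving.data, geom.pixel_pitch_mm, kind="projection")
        if distortion is not None:
            proj = apply_distortion(proj, distortion)
        return proj, _truth(geom, self.tumor_center + disp)


def marker_projection_template(
    geometry: ProjectionGeometry, marker_diameter_mm: float = 5.5, margin_px: int = 2
) -> np.ndarray:
    """Ideal detector-plane template of a projected marker sphere.

    The line integral through a sphere of radius r at transverse offset ρ
    is the chord length 2·sqrt(r² − ρ²); the template is that chord map at
    the detector magnification and pixel pitch. NCC is affine-invariant in
    intensity, so the density scale is irrelevant.
    """
    r_px = (marker_diameter_mm / 2.0) * geometry.magnification / geometry.pixel_pitch_mm
    half = int(np.ceil(r_px)) + margin_px
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    rho2 = (xx**2 + yy**2).astype(float)
    chord = 2.0 * np.sqrt(np.clip(r_px**2 - rho2, 0.0, None))
    return chord
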