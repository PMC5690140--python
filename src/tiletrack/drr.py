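"""Digitally reconstructed radiographs by ray tracing.

A DRR pixel is the line integral of the (trilinearly interpolated) voxel
attenuation along the ray from the source to that pixel, approximated by
midpoint sampling at a fixed step. Pixel values are raw attenuation
integrals (density·mm), not exponentiated transmission: the downstream
matching is intensity-map agnostic (CLAHE plus per-tile linear fits absorb
any monotone display map) and integrals keep the engine exactly linear in
the volume, which the compositing of background and tumor DRRs relies on.

This module also splits a planning volume into a background-only and a
tumor-only volume using the planning tumor contour, mirroring the two-DRR
preprocessing of the tracking method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .geometry import ProjectionGeometry
from .images import Image2D

__all__ = ["Volume3D", "split_volume", "compute_drr", "crop_to_support"]


@dataclass
class Volume3D:
    """Scalar voxel grid in physical coordinates.

    ``data`` is indexed [ix, iy, iz]; the world position of voxel (i,j,k)
    is ``origin + (i,j,k) * spacing`` (millimetres). ``origin`` is the
    center of voxel (0,0,0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on every axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D requires finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center extent (lo, hi) in world mm."""
        hi = self.origin + (np.array(self.data.shape) - 1) * self.spacing
        return self.origin.copy(), hi

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing.copy(), self.origin.copy())


def _check_same_grid(a: Volume3D, b: Volume3D) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(
        a.origin, b.origin
    ):
        raise ValueError("volumes are not on the same grid")


def split_volume(
    ct: Volume3D,
    tumor_mask: Volume3D,
    fill_mode: Literal["shell-mean", "constant"] = "shell-mean",
    fill_value: float | None = None,
    shell_voxels: int = 2,
) -> tuple[Volume3D, Volume3D]:
    """Split a planning volume into background-only and tumor-only volumes.

    ``background`` equals the CT outside the tumor contour; inside the
    contour the excised voxels are filled either with a constant
    (``fill_mode="constant"``, value ``fill_value``) or with the mean CT
    value over a ``shell_voxels``-thick shell just outside the contour
    (``fill_mode="shell-mean"``, the default — in lung the shell mean is
    the surrounding lung density, so the background DRR shows no hole).
    ``tumor_only`` equals the CT inside the contour and zero attenuation
    outside.
    """
    _check_same_grid(ct, tumor_mask)
    mask = tumor_mask.data > 0.5
    background = ct.data.copy()
    tumor_only = np.zeros_like(ct.data)
    if mask.any():
        if fill_mode == "constant":
            if fill_value is None:
                raise ValueError("constant fill requires fill_value")
            fill = float(fill_value)
        elif fill_mode == "shell-mean":
            shell = ndimage.binary_dilation(mask, iterations=shell_voxels) & ~mask
            if not shell.any():
                raise ValueError("tumor mask leaves no boundary shell")
            fill = float(ct.data[shell].mean())
        else:
            raise ValueError(f"unknown fill_mode {fill_mode!r}")
        background[mask] = fill
        tumor_only[mask] = ct.data[mask]
    return (
        Volume3D(background, ct.spacing, ct.origin),
        Volume3D(tumor_only, ct.spacing, ct.origin),
    )


def _ray_box_range(source, dirs, lo, hi):
    """Entry/exit parameters of rays against an axis-aligned box (slab test)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (lo[None, :] - source[None, :]) / dirs
        t1 = (hi[None, :] - source[None, :]) / dirs
    # Rays parallel to a slab: inside -> (-inf, +inf); outside -> empty.
    parallel = dirs == 0.0
    if parallel.any():
        inside = (source[None, :] >= lo[None, :]) & (source[None, :] <= hi[None, :])
        t0 = np.where(parallel, np.where(inside, -np.inf, np.inf), t0)
        t1 = np.where(parallel, np.where(inside, np.inf, -np.inf), t1)
    tmin = np.minimum(t0, t1).max(axis=1)
    tmax = np.maximum(t0, t1).min(axis=1)
    return tmin, tmax


def compute_drr(
    volume: Volume3D,
    geometry: ProjectionGeometry,
    kind: str = "background-drr",
    chunk_rays: int = 4096,
) -> Image2D:
    """Ray trace a volume onto the detector.

    Each pixel accumulates trilinearly interpolated attenuation at midpoint
    samples spaced ``geometry.step_mm`` along its ray, multiplied by the
    step length. Rays missing the volume's bounding box yield 0.
    """
    rows, cols = geometry.detector_shape
    source, beam, e_u, e_v = geometry.basis()
    vc, uc = geometry.detector_center_px()
    pitch = geometry.pixel_pitch_mm
    step = geometry.step_mm

    u_mm = (np.arange(cols) - uc) * pitch
    v_mm = (np.arange(rows) - vc) * pitch
    det_center = source + geometry.sdd_mm * beam
    # Pixel world positions, flattened row-major: (rows*cols, 3)
    pix = (
        det_center[None, None, :]
        + v_mm[:, None, None] * e_v[None, None, :]
        + u_mm[None, :, None] * e_u[None, None, :]
    ).reshape(-1, 3)

    dirs = pix - source[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    lo, hi = volume.bounds()
    tmin, tmax = _ray_box_range(source, dirs, lo, hi)
    tmin = np.maximum(tmin, 0.0)
    hit = tmax > tmin

    out = np.zeros(rows * cols)
    hit_idx = np.flatnonzero(hit)
    if hit_idx.size:
        spacing = volume.spacing
        origin = volume.origin
        for start in range(0, hit_idx.size, chunk_rays):
            sel = hit_idx[start : start + chunk_rays]
            a = tmin[sel]
            b = tmax[sel]
            nmax = int(np.ceil((b - a).max() / step))
            ts = a[:, None] + (np.arange(nmax)[None, :] + 0.5) * step
            valid = ts < b[:, None]
            pts = source[None, None, :] + ts[:, :, None] * dirs[sel][:, None, :]
            idx = (pts - origin[None, None, :]) / spacing[None, None, :]
            vals = ndimage.map_coordinates(
                volume.data,
                [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
                order=1,
                mode="constant",
                cval=0.0,
            ).reshape(ts.shape)
            out[sel] = (vals * valid).sum(axis=1) * step

    return Image2D(out.reshape(rows, cols), pixel_pitch_mm=pitch, kind=kind)


def crop_to_support(volume: Volume3D, margin_voxels: int = 1) -> Volume3D:
    """Crop a mostly-zero volume to the bounding box of its nonzero voxels.

    The cropped volume keeps the world frame (origin shifted accordingly),
    so its DRRs match the full volume's to numerical tolerance; ray tracing
    a tight tumor-only volume is much cheaper than the full grid.
    """
    nz = np.nonzero(volume.data)
    if len(nz[0]) == 0:
        raise ValueError("volume has no nonzero support")
    lo = [max(int(n.min()) - margin_voxels, 0) for n in nz]
    hi = [min(int(n.max()) + margin_voxels + 1, s) for n, s in zip(nz, volume.shape)]
    data = volume.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    origin = volume.index_to_world(np.array(lo, dtype=float))
    return Volume3D(data, volume.spacing.copy(), origin)
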