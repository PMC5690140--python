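"""Projection geometry of an on-board kV imaging system.

The machine rotates about the superior-inferior (z) axis. The X-ray source
sits at SAD millimetres from the isocenter and the flat-panel detector at
SDD millimetres from the source, perpendicular to the central ray. The
*imaging angle* (gantry angle plus imager offset) selects the direction of
the central ray in the axial plane.

Conventions (fixed so that tests can be bit-exact):

* World coordinates are physical millimetres with the isocenter at the
  origin; +z is superior.
* At imaging angle 0 the source is at (0, -SAD, 0) and the central ray
  points along +y. Positive angles rotate the source counter-clockwise
  (viewed from +z).
* Detector axes: u = columns, increasing with the rotated +x direction;
  v = rows, increasing with +z. Pixel coordinates are 0-based pixel
  centers; the central ray hits the detector at pixel
  ((rows-1)/2, (cols-1)/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "ProjectionGeometry",
    "ProjectedPoint",
    "project_point",
    "pixels_to_mm",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Source/detector layout of a kV imager.

    Defaults are the Vero-type geometry: SAD 1000 mm, SDD 1876 mm,
    0.4 mm detector pixels.
    """

    sad_mm: float = 1000.0
    sdd_mm: float = 1876.0
    pixel_pitch_mm: float = 0.4
    detector_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    gantry_deg: float = 0.0
    imager_deg: float = 0.0
    step_mm: float = 1.0  # ray-march step for DRR computation

    def __post_init__(self) -> None:
        if not (0.0 < self.sad_mm < self.sdd_mm):
            raise ValueError("require 0 < SAD < SDD")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.step_mm <= 0:
            raise ValueError("ray-march step must be positive")
        rows, cols = self.detector_shape
        if rows < 1 or cols < 1:
            raise ValueError("detector must have at least one pixel per axis")

    @property
    def imaging_angle_deg(self) -> float:
        """Absolute direction of the central ray (gantry + imager offset)."""
        return self.gantry_deg + self.imager_deg

    @property
    def magnification(self) -> float:
        """Detector magnification of an object in the isocenter plane."""
        return self.sdd_mm / self.sad_mm

    def with_angles(self, gantry_deg: float, imager_deg: float = 0.0) -> "ProjectionGeometry":
        return replace(self, gantry_deg=gantry_deg, imager_deg=imager_deg)

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (source, beam_axis, e_u, e_v) in world mm.

        ``beam_axis`` is the unit vector from source towards the isocenter,
        ``e_u``/``e_v`` are the detector column/row directions.
        """
        a = np.deg2rad(self.imaging_angle_deg)
        ca, sa = np.cos(a), np.sin(a)
        source = np.array([self.sad_mm * sa, -self.sad_mm * ca, 0.0])
        beam = np.array([-sa, ca, 0.0])
        e_u = np.array([ca, sa, 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        return source, beam, e_u, e_v

    def detector_center_px(self) -> tuple[float, float]:
        rows, cols = self.detector_shape
        return (rows - 1) / 2.0, (cols - 1) / 2.0


class ProjectedPoint(NamedTuple):
    """Perspective image of a world point on the detector."""

    u_mm: float
    v_mm: float
    u_px: float
    v_px: float


def project_point(geometry: ProjectionGeometry, point_mm) -> ProjectedPoint:
    """Project a 3D world point through the source onto the detector plane.

    Returns millimetres on the detector (0 at the central ray) and the
    corresponding 0-based pixel coordinates. Points at or behind the source
    plane are rejected.
    """
    p = np.asarray(point_mm, dtype=float)
    source, beam, e_u, e_v = geometry.basis()
    d = p - source
    depth = float(d @ beam)
    if depth <= 0:
        raise ValueError("point is at or behind the source plane")
    u_mm = geometry.sdd_mm * float(d @ e_u) / depth
    v_mm = geometry.sdd_mm * float(d @ e_v) / depth
    vc, uc = geometry.detector_center_px()
    return ProjectedPoint(
        u_mm=u_mm,
        v_mm=v_mm,
        u_px=u_mm / geometry.pixel_pitch_mm + uc,
        v_px=v_mm / geometry.pixel_pitch_mm + vc,
    )


def pixels_to_mm(delta_px, geometry: ProjectionGeometry):
    """Convert a detector-pixel offset to millimetres in the isocenter plane.

    Δmm = Δpx · pitch · SAD/SDD (inverse magnification); linear, so it
    applies per axis and to arrays.
    """
    return np.asarray(delta_px, dtype=float) * geometry.pixel_pitch_mm * (
        geometry.sad_mm / geometry.sdd_mm
    )
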