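"""Build the digital torso phantom and compute its DRRs.

Rasterizes the default torso (lungs, ribs, heart sphere, 3 cm cylindrical
tumor, three 5.5 mm markers), splits it into background-only and
tumor-only volumes using the tumor contour, and ray-traces both onto a
256x256 detector at the Vero-type geometry.
"""

import numpy as np

from tiletrack import (
    PhantomSpec,
    ProjectionGeometry,
    build_torso_volume,
    compute_drr,
    crop_to_support,
    split_volume,
)

spec = PhantomSpec()
ct, tumor_mask, marker_centers = build_torso_volume(spec)
print(f"phantom volume: {ct.shape} voxels at {tuple(ct.spacing)} mm spacing")
print(f"tissue attenuation values present: {np.unique(ct.data)}")

voxel_volume = np.prod(ct.spacing)
analytic = np.pi * (spec.tumor_diameter_mm / 2) ** 2 * spec.tumor_height_mm
print(
    f"tumor mask volume {tumor_mask.data.sum() * voxel_volume:.0f} mm^3 "
    f"vs analytic cylinder {analytic:.0f} mm^3"
)

background, tumor_only = split_volume(ct, tumor_mask)
geometry = ProjectionGeometry(
    pixel_pitch_mm=1.6, detector_shape=(256, 256), gantry_deg=0.0, imager_deg=45.0
)
bg_drr = compute_drr(background, geometry)
tumor_drr = compute_drr(crop_to_support(tumor_only), geometry, kind="tumor-drr")

print(f"background DRR range: {bg_drr.data.min():.1f} .. {bg_drr.data.max():.1f} density*mm")
print(f"tumor DRR peak line integral: {tumor_drr.data.max():.1f} density*mm")
# The background DRR is the tumor-removed reference the tracker matches
# against; the tumor DRR is the template located on the residual image.
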