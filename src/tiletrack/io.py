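"""Reading and writing volumes, projection images and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .drr import Volume3D
from .images import Image2D

__all__ = [
    "read_volume",
    "write_volume",
    "read_projection",
    "write_projection",
    "write_trajectory_csv",
    "write_summary_csv",
]


def read_volume(path) -> Volume3D:
    """Load a MetaImage (.mha/.mhd) or NRRD volume into world-mm frame."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(float)
    return Volume3D(data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))


def write_volume(volume: Volume3D, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_projection(path, pixel_pitch_mm: float = 1.0) -> Image2D:
    """Read a projection image (TIFF/PNG); float sidecars (.npy) pass through."""
    p = Path(path)
    if p.suffix == ".npy":
        data = np.load(p)
    else:
        data = tifffile.imread(str(p)) if p.suffix in (".tif", ".tiff") else None
        if data is None:
            import imageio.v3 as iio  # PNG fallback without a hard dependency

            data = iio.imread(str(p))
    return Image2D(np.asarray(data, dtype=float), pixel_pitch_mm=pixel_pitch_mm)


def write_projection(image: Image2D, path, float_sidecar: bool = True) -> None:
    """Write a 16-bit TIFF (range-scaled) plus a lossless float sidecar."""
    p = Path(path)
    data = image.data
    lo, hi = float(data.min()), float(data.max())
    scale = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    tifffile.imwrite(str(p), (scale * 65535.0 + 0.5).astype(np.uint16))
    if float_sidecar:
        np.save(str(p.with_suffix(p.suffix + ".npy")), data.astype(np.float64))


def write_trajectory_csv(trajectories, path) -> None:
    frames = [t.to_dataframe() for t in trajectories]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_summary_csv(summary, path) -> None:
    df = summary.per_angle.copy()
    df.loc[len(df)] = {
        "gantry_deg": "overall",
        "imager_deg": "",
        "max_mm": summary.overall_max_mm,
        "mean_mm": summary.overall_mean_mm,
        "n_frames": int(df["n_frames"].sum()),
    }
    df.to_csv(path, index=False)
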