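"""Lightweight 2D image container with provenance tagging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D", "as_image_array"]


@dataclass
class Image2D:
    """A scalar detector-plane image.

    ``kind`` records provenance: "projection", "background-drr",
    "tumor-drr" or "residual".
    """

    data: np.ndarray
    pixel_pitch_mm: float = 1.0
    kind: str = "projection"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 1:
            raise ValueError("Image2D requires a non-empty 2D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Image2D requires finite pixel values")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def as_image_array(image) -> np.ndarray:
    """Accept an Image2D or a bare 2D array and return the float ndarray."""
    if isinstance(image, Image2D):
        return image.data
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    return arr
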