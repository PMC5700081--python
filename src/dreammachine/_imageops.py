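"""Shared raster helpers: one declared resampling convention for the package.

All resampling is bilinear with half-pixel-centre alignment and edge-clamped
out-of-range samples; images are H x W x 3 float64 on a [0, 255] working
range.  Keeping a single convention here means every octave resize, zoom and
flow warp agrees about sub-pixel geometry.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

WORKING_RANGE = (0.0, 255.0)


def as_image(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    return x


def clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, *WORKING_RANGE)


def resize_bilinear(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Resize to (height, width); identity sizes return a copy bit-exactly."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    nh, nw = size
    if (nh, nw) == (h, w):
        return image.copy()
    # half-pixel centres: output pixel j samples input at (j + .5) * s - .5
    rows = (np.arange(nh) + 0.5) * (h / nh) - 0.5
    cols = (np.arange(nw) + 0.5) * (w / nw) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    if image.ndim == 2:
        return map_coordinates(image, [rr, cc], order=1, mode="nearest")
    out = np.empty((nh, nw, image.shape[2]))
    for c in range(image.shape[2]):
        out[..., c] = map_coordinates(image[..., c], [rr, cc], order=1, mode="nearest")
    return out


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luma conversion (Rec. 601 weights) for flow estimation."""
    image = np.asarray(image, dtype=np.float64)
    return image @ np.array([0.299, 0.587, 0.114])
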