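"""Image readers and writers.

All images travel through the pipeline as float64 on the 0-255 scale.
8-bit files map 1:1; 16-bit files are rescaled by 255/65535; RGB inputs
are collapsed to luminance with a logged warning.  Writing clamps to
[0, 255] and rounds to uint8; the format follows the file extension
(PNG or TIFF).
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("curvefuse")

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def read_gray(path) -> np.ndarray:
    """Load a PNG/TIFF as a float64 grayscale image on the 0-255 scale."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
        logger.warning("RGB input %s converted to luminance", path)
        arr = arr.astype(np.float64) @ _LUMA
        if arr.max() > 255:  # 16-bit color
            arr *= 255.0 / 65535.0
        return arr
    if arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) * (255.0 / 65535.0)
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")


def write_gray(img: np.ndarray, path) -> None:
    """Clamp to [0, 255], round to uint8, write by extension."""
    path = Path(path)
    out = np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)
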