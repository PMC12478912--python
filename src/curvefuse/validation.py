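"""Input validation shared across modules.

All public operations work on 2-D float64 arrays on the 0-255 intensity
scale.  Intermediate subbands are signed and unclamped; clamping to
[0, 255] happens only at image export.
"""

from __future__ import annotations

import numpy as np


def as_image(img, name: str = "image") -> np.ndarray:
    """Coerce to a finite 2-D float64 array.

    Raises ValueError on empty, non-2-D or non-finite input.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or Inf")
    return arr


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "images") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} must have equal shapes, got {a.shape} vs {b.shape}")
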