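"""Multiscale decomposition and reconstruction.

Two backends are provided:

* the Gaussian residual pyramid used by the fusion pipeline — at each
  level the detail subband is the residual against a heavily smoothed
  copy (``H_i = L_{i-1} - G_sigma(L_{i-1})``) and the next approximation
  is the smoothed image decimated by 2 (``L_i = down2(G_sigma(L_{i-1}))``);
* the classical Burt–Adelson Laplacian pyramid, which stores the exact
  residual against the expanded next level and is therefore perfectly
  invertible.

The Gaussian residual scheme is *not* perfect-reconstruction (down2
followed by upsampling is not the identity), but with a large smoothing
width (default sigma = 20) the resampling error on the smoothed field is
far below the 0-255 intensity scale.

Conventions, fixed for reproducibility:

* Gaussian kernel truncated at radius ceil(3*sigma), reflective boundary;
* decimation keeps every second pixel starting at index 0, so an image of
  height h decimates to ceil(h/2) rows (the smoothing step is the
  anti-alias filter);
* upsampling is bilinear, resized to the exact recorded target shape;
* subbands are signed and never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter
from skimage.transform import resize

from .validation import as_image

#: Burt–Adelson 5-tap binomial low-pass kernel.
BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class DecompositionPyramid:
    """Detail subbands H_1..H_L plus the terminal low-frequency image.

    ``details[i]`` has the shape of level i (i.e. ``level_shapes[i]``),
    ``low`` the shape of ``level_shapes[levels]``.
    """

    details: list[np.ndarray]
    low: np.ndarray
    level_shapes: list[tuple[int, int]]
    sigma: float | None = None
    levels: int = field(default=0)

    def __post_init__(self) -> None:
        if self.levels == 0:
            self.levels = len(self.details)
        self.validate()

    def validate(self) -> None:
        if len(self.details) != self.levels:
            raise ValueError("number of detail subbands must equal levels")
        if len(self.level_shapes) != self.levels + 1:
            raise ValueError("level_shapes must record L_0..L_L")
        for i, h in enumerate(self.details):
            if h.shape != self.level_shapes[i]:
                raise ValueError(
                    f"detail {i + 1} has shape {h.shape}, "
                    f"expected {self.level_shapes[i]}"
                )
        if self.low.shape != self.level_shapes[self.levels]:
            raise ValueError("low image shape does not match level_shapes")


def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with a normalized 2-D Gaussian (reflective boundary).

    Kernel truncated at radius ceil(3*sigma).  Constants are preserved to
    floating precision and the output range never exceeds the input range.
    """
    img = as_image(img)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = math.ceil(3.0 * sigma)
    return gaussian_filter(img, sigma, mode="reflect", radius=radius)


def downsample2(img: np.ndarray) -> np.ndarray:
    """Keep every second pixel starting at index 0 (ceiling convention)."""
    img = as_image(img)
    return img[::2, ::2].copy()


def upsample2(img: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling by 2 to an exact target shape.

    ``target_shape`` must lie componentwise in [2*shape - 1, 2*shape],
    matching the ceiling-halving decimation of :func:`downsample2`.
    """
    img = as_image(img)
    th, tw = int(target_shape[0]), int(target_shape[1])
    h, w = img.shape
    if not (2 * h - 1 <= th <= 2 * h) or not (2 * w - 1 <= tw <= 2 * w):
        raise ValueError(
            f"target shape {(th, tw)} incompatible with upsampling {img.shape} by 2"
        )
    return resize(
        img, (th, tw), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def decompose(img: np.ndarray, levels: int = 3, sigma: float = 20.0) -> DecompositionPyramid:
    """Gaussian residual pyramid: H_i = L_{i-1} - G(L_{i-1}); L_i = down2(G(L_{i-1}))."""
    img = as_image(img)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    shapes = [img.shape]
    for _ in range(levels):
        h, w = shapes[-1]
        shapes.append((math.ceil(h / 2), math.ceil(w / 2)))
    if shapes[-1][0] < 2 or shapes[-1][1] < 2:
        raise ValueError(
            f"image of shape {img.shape} too small for {levels} levels "
            f"(terminal shape {shapes[-1]} < 2x2)"
        )
    details = []
    current = img
    for _ in range(levels):
        smoothed = gaussian_smooth(current, sigma)
        details.append(current - smoothed)
        current = downsample2(smoothed)
    return DecompositionPyramid(
        details=details,
        low=current,
        level_shapes=[tuple(s) for s in shapes],
        sigma=sigma,
        levels=levels,
    )


def reconstruct(
    low: np.ndarray,
    details: list[np.ndarray],
    level_shapes: list[tuple[int, int]],
) -> np.ndarray:
    """Coarse-to-fine synthesis: R_{i-1} = up2(R_i, shape_{i-1}) + H_i.

    The recursive form is the unique shape-consistent reading of the
    single-expansion synthesis formula for more than one level.
    """
    low = as_image(low, "low")
    levels = len(details)
    if len(level_shapes) != levels + 1:
        raise ValueError("level_shapes must record L_0..L_L")
    if low.shape != tuple(level_shapes[levels]):
        raise ValueError("low image shape does not match level_shapes")
    current = low
    for i in range(levels, 0, -1):
        target = tuple(level_shapes[i - 1])
        det = as_image(details[i - 1], f"detail {i}")
        if det.shape != target:
            raise ValueError(
                f"detail {i} has shape {det.shape}, expected {target}"
            )
        current = upsample2(current, target) + det
    return current


def _lp_smooth(img: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Separable low-pass filtering with reflective boundary."""
    out = correlate1d(img, h, axis=0, mode="reflect")
    return correlate1d(out, h, axis=1, mode="reflect")


def _lp_expand(img: np.ndarray, target_shape: tuple[int, int], h: np.ndarray) -> np.ndarray:
    """Zero-insertion upsampling followed by interpolation with 2*h per axis.

    Boundary mode "mirror" (no edge duplication) keeps the even/odd
    parity of the zero-stuffed lattice, so constants expand to constants.
    """
    th, tw = target_shape
    up = np.zeros((th, tw), dtype=np.float64)
    up[::2, ::2] = img
    out = correlate1d(up, 2.0 * h, axis=0, mode="mirror")
    return correlate1d(out, 2.0 * h, axis=1, mode="mirror")


def lp_decompose(
    img: np.ndarray, levels: int = 3, h: np.ndarray | None = None
) -> DecompositionPyramid:
    """Classical Laplacian pyramid (exactly invertible).

    ``H_i = L_i - expand(L_{i+1})`` with ``L_{i+1} = down2(L_i * h)``;
    the stored residual makes :func:`lp_reconstruct` exact by construction.
    """
    img = as_image(img)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h = BINOMIAL5 if h is None else np.asarray(h, dtype=np.float64)
    if h.ndim != 1 or not np.isclose(h.sum(), 1.0):
        raise ValueError("h must be a 1-D normalized low-pass kernel")
    shapes = [img.shape]
    for _ in range(levels):
        hh, ww = shapes[-1]
        shapes.append((math.ceil(hh / 2), math.ceil(ww / 2)))
    if shapes[-1][0] < 2 or shapes[-1][1] < 2:
        raise ValueError(f"image too small for {levels} levels")
    details = []
    current = img
    for i in range(levels):
        nxt = downsample2(_lp_smooth(current, h))
        details.append(current - _lp_expand(nxt, shapes[i], h))
        current = nxt
    return DecompositionPyramid(
        details=details,
        low=current,
        level_shapes=[tuple(s) for s in shapes],
        sigma=None,
        levels=levels,
    )


def lp_reconstruct(pyr: DecompositionPyramid, h: np.ndarray | None = None) -> np.ndarray:
    """Exact inverse of :func:`lp_decompose` (same kernel required)."""
    h = BINOMIAL5 if h is None else np.asarray(h, dtype=np.float64)
    current = pyr.low
    for i in range(pyr.levels, 0, -1):
        target = tuple(pyr.level_shapes[i - 1])
        current = _lp_expand(current, target, h) + pyr.details[i - 1]
    return current
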