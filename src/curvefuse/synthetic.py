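"""Seeded synthetic phantoms and analytic fixtures.

A phantom pair emulates a co-registered anatomical modality pair of a
head section:

* image A (MRI-like): smooth soft-tissue contrast inside the skull —
  Gaussian tissue blobs on a mid-gray base, a bright fluid (ventricle)
  ellipse, and a dark ring where the bone sits;
* image B (CT-like): a bright high-intensity ring at the same
  coordinates (bone) with a flat, low-contrast interior.

The shared ring/interior geometry guarantees pixelwise co-registration;
independent additive Gaussian noise models acquisition noise.  The same
spec always produces bitwise-identical output (a single seeded
generator, no global state).

Analytic fixtures (constant, ramp, checkerboard, impulse, cone, saddle)
back the closed-form tests of the pyramid, curvature and metric layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PhantomSpec:
    """Seeded description of a synthetic co-registered modality pair.

    Geometry defaults scale with the image size: the skull ring is an
    annulus at 0.39-0.43 of the half-diagonal-free radius, tissue blobs
    are Gaussians inside it, the fluid region is a central ellipse.
    noise_sd is the standard deviation of the additive Gaussian noise in
    intensity units (default 2.0; 0 disables noise).
    """

    height: int = 256
    width: int = 256
    seed: int = 0
    noise_sd: float = 2.0
    ring_radii: tuple[float, float] = (0.78, 0.86)  # fractions of min(h, w)/2
    ring_intensity_ct: float = 220.0
    ring_intensity_mri: float = 25.0
    interior_ct: float = 70.0
    tissue_base: float = 90.0
    tissue_blobs: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [
            # (center_y, center_x, width, amplitude), centers as fractions
            (0.38, 0.40, 0.10, 55.0),
            (0.62, 0.58, 0.12, -35.0),
            (0.55, 0.35, 0.08, 40.0),
            (0.40, 0.65, 0.09, 30.0),
        ]
    )
    fluid_center: tuple[float, float] = (0.5, 0.5)
    fluid_axes: tuple[float, float] = (0.16, 0.08)  # fractions of min(h, w)/2
    fluid_intensity: float = 200.0
    background: float = 5.0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8x8")
        r_in, r_out = self.ring_radii
        if not 0 < r_in < r_out <= 1.0:
            raise ValueError("ring radii must satisfy 0 < inner < outer <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.fluid_axes) <= 0:
            raise ValueError("fluid axes must be positive")


def _grids(spec: PhantomSpec):
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return yy, xx, r


def ring_mask(spec: PhantomSpec, dilate: float = 0.0) -> np.ndarray:
    """Boolean mask of the skull annulus, optionally widened by ``dilate`` px."""
    _, _, r = _grids(spec)
    scale = min(spec.height, spec.width) / 2.0
    r_in, r_out = spec.ring_radii[0] * scale, spec.ring_radii[1] * scale
    return (r >= r_in - dilate) & (r <= r_out + dilate)


def make_phantom_pair(spec: PhantomSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (MRI-like, CT-like) pair for the given spec."""
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    yy, xx, r = _grids(spec)
    scale = min(spec.height, spec.width) / 2.0
    r_in = spec.ring_radii[0] * scale
    r_out = spec.ring_radii[1] * scale
    inside = r < r_in
    ring = (r >= r_in) & (r <= r_out)

    # MRI-like: smooth tissue + bright fluid, dark bone
    a = np.full((spec.height, spec.width), spec.background)
    tissue = np.full_like(a, spec.tissue_base)
    for fy, fx, fw, amp in spec.tissue_blobs:
        by, bx = fy * spec.height, fx * spec.width
        bw = fw * min(spec.height, spec.width)
        tissue += amp * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2.0 * bw**2)))
    a[inside] = tissue[inside]
    fy, fx = spec.fluid_center[0] * spec.height, spec.fluid_center[1] * spec.width
    ay, ax = spec.fluid_axes[0] * scale * 2, spec.fluid_axes[1] * scale * 2
    fluid = ((yy - fy) / ay) ** 2 + ((xx - fx) / ax) ** 2 <= 1.0
    a[fluid & inside] = spec.fluid_intensity
    a[ring] = spec.ring_intensity_mri

    # CT-like: bright ring, flat interior
    b = np.full((spec.height, spec.width), spec.background)
    b[inside] = spec.interior_ct
    b[ring] = spec.ring_intensity_ct

    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd, a.shape)
        b = b + rng.normal(0.0, spec.noise_sd, b.shape)
    return np.clip(a, 0.0, 255.0), np.clip(b, 0.0, 255.0)


def analytic_fixtures(size: int = 64) -> dict[str, np.ndarray]:
    """Closed-form test images.

    constant      value 40 everywhere, size x size
    ramp          u(x, y) = x (unit slope along columns)
    checkerboard  the 2x2 image [[0, 255], [255, 0]]
    impulse       zeros with a single 1.0 at the center, 201x201
    cone          u = sqrt((x-c)^2 + (y-c)^2), apex value 0 at the center
    saddle        u = x*y in centered coordinates, scaled into [0, 255]
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    c = (size - 1) / 2.0
    impulse = np.zeros((201, 201))
    impulse[100, 100] = 1.0
    xs, ys = xx - c, yy - c
    saddle = xs * ys
    saddle = (saddle - saddle.min()) / (saddle.max() - saddle.min()) * 255.0
    # cone needs a pixel exactly at the apex -> odd side length
    n = size if size % 2 else size + 1
    cy, cx = np.mgrid[0:n, 0:n].astype(np.float64) - (n - 1) / 2.0
    return {
        "constant": np.full((size, size), 40.0),
        "ramp": xx.copy(),
        "checkerboard": np.array([[0.0, 255.0], [255.0, 0.0]]),
        "impulse": impulse,
        "cone": np.sqrt(cx**2 + cy**2),
        "saddle": saddle,
    }
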