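"""Fusion rules and the end-to-end pipeline.

Pipeline: decompose both co-registered sources into detail subbands and
a terminal low-frequency image; fuse the low-frequency images by
weighted averaging (brightness consistency); sharpen the terminal-level
detail subbands of both sources with the mean-curvature filter; fuse
detail subbands pixelwise by the max-absolute rule (edge retention);
reconstruct coarse-to-fine and clamp to [0, 255] at export.

Ablation variants: weighted averaging for the detail subbands instead of
max-absolute, and taking the low-frequency image from a single source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .curvature import FlowParams, apply_variant
from .pyramid import decompose, lp_decompose, lp_reconstruct, reconstruct
from .validation import as_image, check_same_shape

FILTER_SCOPES = ("level_L_only", "all_levels", "none")
HIGH_RULES = ("max_abs", "weighted")
LOW_MODES = ("both", "a_only", "b_only")
BACKENDS = ("gaussian_residual", "laplacian_pyramid")


@dataclass
class FusionConfig:
    """All tunable parameters of the fusion pipeline.

    Defaults are the reference operating point: three levels, smoothing
    width sigma = 20, equal low-frequency weights (alpha = 0.5),
    mean-curvature flow at dt = 0.0005 for 15 iterations applied to the
    terminal-level detail subbands only, max-absolute detail fusion.
    """

    levels: int = 3
    sigma: float = 20.0
    alpha: float = 0.5
    flow: FlowParams = field(default_factory=FlowParams)
    filter_scope: str = "level_L_only"
    high_rule: str = "max_abs"
    low_mode: str = "both"
    backend: str = "gaussian_residual"

    def validate(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.filter_scope not in FILTER_SCOPES:
            raise ValueError(f"filter_scope must be one of {FILTER_SCOPES}")
        if self.high_rule not in HIGH_RULES:
            raise ValueError(f"high_rule must be one of {HIGH_RULES}")
        if self.low_mode not in LOW_MODES:
            raise ValueError(f"low_mode must be one of {LOW_MODES}")
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")
        self.flow.validate()


def fuse_low(la: np.ndarray, lb: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Weighted average alpha*LA + (1-alpha)*LB of low-frequency images."""
    la, lb = as_image(la, "LA"), as_image(lb, "LB")
    check_same_shape(la, lb, "low-frequency images")
    return alpha * la + (1.0 - alpha) * lb


def fuse_high_maxabs(ha: np.ndarray, hb: np.ndarray) -> np.ndarray:
    """Pixelwise coefficient of larger magnitude; ties go to the second input.

    The strict inequality |HA| > |HB| selects HA, so exact-magnitude ties
    (including zeros) resolve to HB — fixed for reproducibility.
    """
    ha, hb = as_image(ha, "HA"), as_image(hb, "HB")
    check_same_shape(ha, hb, "detail subbands")
    return np.where(np.abs(ha) > np.abs(hb), ha, hb)


def fuse_high_weighted(ha: np.ndarray, hb: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Weighted averaging of detail subbands (ablation variant)."""
    return fuse_low(ha, hb, alpha)


def _filter_details(details: list[np.ndarray], config: FusionConfig) -> list[np.ndarray]:
    if config.filter_scope == "none" or config.flow.variant == "none":
        return details
    if config.filter_scope == "all_levels":
        idx = set(range(len(details)))
    else:  # level_L_only
        idx = {len(details) - 1}
    return [
        apply_variant(d, config.flow) if i in idx else d
        for i, d in enumerate(details)
    ]


def fuse_images(a: np.ndarray, b: np.ndarray, config: FusionConfig | None = None) -> np.ndarray:
    """Fuse two co-registered grayscale images; returns floats in [0, 255].

    Both sources' selected detail subbands are curvature-filtered before
    the fusion rule (filter-then-fuse, symmetric in the sources).
    """
    config = config or FusionConfig()
    config.validate()
    a, b = as_image(a, "A"), as_image(b, "B")
    check_same_shape(a, b, "source images")

    if config.backend == "gaussian_residual":
        pa = decompose(a, config.levels, config.sigma)
        pb = decompose(b, config.levels, config.sigma)
    else:
        pa = lp_decompose(a, config.levels)
        pb = lp_decompose(b, config.levels)

    if config.low_mode == "a_only":
        low = pa.low
    elif config.low_mode == "b_only":
        low = pb.low
    else:
        low = fuse_low(pa.low, pb.low, config.alpha)

    da = _filter_details(pa.details, config)
    db = _filter_details(pb.details, config)
    if config.high_rule == "max_abs":
        details = [fuse_high_maxabs(x, y) for x, y in zip(da, db)]
    else:
        details = [fuse_high_weighted(x, y, config.alpha) for x, y in zip(da, db)]

    if config.backend == "gaussian_residual":
        fused = reconstruct(low, details, pa.level_shapes)
    else:
        pa_fused = replace_pyramid(pa, low, details)
        fused = lp_reconstruct(pa_fused)
    return np.clip(fused, 0.0, 255.0)


def replace_pyramid(pyr, low, details):
    """Pyramid with the same geometry but fused coefficients."""
    from .pyramid import DecompositionPyramid

    return DecompositionPyramid(
        details=list(details),
        low=low,
        level_shapes=list(pyr.level_shapes),
        sigma=pyr.sigma,
        levels=pyr.levels,
    )


#: variant label -> config overrides, in report order
ABLATION_VARIANTS = {
    "full": {},
    "weighted_high": {"high_rule": "weighted"},
    "low_a_only": {"low_mode": "a_only"},
    "low_b_only": {"low_mode": "b_only"},
}


def ablation_suite(
    a: np.ndarray, b: np.ndarray, base_config: FusionConfig | None = None
) -> pd.DataFrame:
    """Metric table for the full method and its ablated variants.

    Rows: full method, weighted-average detail fusion, and single-source
    low-frequency (A only / B only).  Columns: variant label plus the
    nine quality scores.
    """
    base_config = base_config or FusionConfig()
    rows = []
    for label, overrides in ABLATION_VARIANTS.items():
        cfg = replace(base_config, **overrides)
        fused = fuse_images(a, b, cfg)
        row = {"variant": label}
        row.update(metrics.report(fused, a, b).as_row())
        rows.append(row)
    return pd.DataFrame(rows)
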