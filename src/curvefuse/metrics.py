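"""Objective fusion-quality metrics.

Nine scores for a (fused F, source A, source B) triplet:

API      mean intensity of F
SD       population standard deviation of F (divisor M*N)
AG       mean gradient magnitude of F (forward differences)
Entropy  Shannon entropy of the 256-bin histogram of F, in bits
MIF      MI(F,A) + MI(F,B) from 256x256 joint histograms, in bits
FS1      symmetry of the information split between the sources
Corr     Pearson correlation of F with the sources
SF       spatial frequency, sqrt(RF^2 + CF^2) of first differences
QABF     Sobel-based edge-preservation score in [0, 1]

Conventions (fixed for reproducibility):

* histogram-based scores (Entropy, MIF, FS1) quantize to uint8 first
  (round-half-even, clamp to [0, 255]) so the 256-level histograms are
  well defined; gradient scores (AG, SF, QABF) use the floating image;
* AG and SF sum squared forward differences over valid index pairs only
  but keep the printed 1/(M*N) divisor by default; a "valid" divisor
  switch is provided;
* FS1 as printed, (MI(F,A)-MI(F,B))/(MI(F,A)+MI(F,B)), is bounded by 1,
  yet reported fusion-symmetry values in the literature lie in [1.5, 2];
  the default "table_scale" variant 2 - |MI(F,A)/(MIF) - 0.5| matches
  that scale, and the printed form stays available;
* Corr reports the mean of Corr(F,A) and Corr(F,B) by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import sobel

from .validation import as_image, check_same_shape

COLUMNS = ["API", "SD", "AG", "Entropy", "MIF", "FS1", "Corr", "SF", "QABF"]


def quantize_u8(img: np.ndarray) -> np.ndarray:
    """Round-half-even to the nearest integer, clamp to [0, 255], uint8."""
    img = as_image(img)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class MetricReport:
    """One row of the evaluation table."""

    api: float
    sd: float
    ag: float
    entropy: float
    mif: float
    fs1: float
    corr: float
    sf: float
    qabf: float

    def as_row(self) -> dict[str, float]:
        return dict(zip(COLUMNS, asdict(self).values()))

    def to_json(self, **extra) -> str:
        payload = self.as_row()
        payload.update(extra)
        return json.dumps(payload, indent=2)


def api(img: np.ndarray) -> float:
    """Average pixel intensity."""
    return float(np.mean(as_image(img)))


def sd(img: np.ndarray) -> float:
    """Population standard deviation (divisor M*N)."""
    return float(np.std(as_image(img)))


def ag(img: np.ndarray, divisor: str = "mn") -> float:
    """Average gradient: mean of sqrt(gx^2 + gy^2), forward differences.

    Differences exist only on the first M-1 rows and N-1 columns; the sum
    runs over that valid region.  divisor="mn" (default) divides by M*N
    as printed; divisor="valid" divides by the number of valid pixels.
    """
    f = as_image(img)
    gx = f[:-1, 1:] - f[:-1, :-1]
    gy = f[1:, :-1] - f[:-1, :-1]
    mag = np.sqrt(gx * gx + gy * gy)
    if divisor == "mn":
        return float(mag.sum() / f.size)
    if divisor == "valid":
        return float(mag.mean())
    raise ValueError("divisor must be 'mn' or 'valid'")


def entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin histogram of the uint8 image."""
    q = quantize_u8(img)
    counts = np.bincount(q.ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def joint_histogram(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """256x256 joint count grid of two uint8-quantized images."""
    qa = quantize_u8(a).ravel().astype(np.intp)
    qb = quantize_u8(b).ravel().astype(np.intp)
    counts = np.bincount(qa * 256 + qb, minlength=256 * 256)
    return counts.reshape(256, 256)


def mutual_information(f: np.ndarray, a: np.ndarray) -> float:
    """MI in bits from the 256x256 joint histogram; 0-cells contribute 0."""
    f_, a_ = as_image(f), as_image(a)
    check_same_shape(f_, a_)
    joint = joint_histogram(f_, a_) / f_.size
    pf = joint.sum(axis=1)
    pa = joint.sum(axis=0)
    outer = np.outer(pf, pa)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))


def mif(f: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Total information retained from both sources: MI(F,A) + MI(F,B)."""
    return mutual_information(f, a) + mutual_information(f, b)


def fs1(f: np.ndarray, a: np.ndarray, b: np.ndarray, variant: str = "table_scale") -> float:
    """Fusion symmetry of the information split.

    variant="printed": (MI(F,A) - MI(F,B)) / (MI(F,A) + MI(F,B)), in [-1, 1].
    variant="table_scale" (default): 2 - |MI(F,A)/(MI(F,A)+MI(F,B)) - 0.5|,
    in [1.5, 2] with 2 meaning a perfectly balanced split.
    """
    mi_a = mutual_information(f, a)
    mi_b = mutual_information(f, b)
    total = mi_a + mi_b
    if total == 0:
        raise ValueError("FS1 undefined: no information shared with either source")
    if variant == "printed":
        return (mi_a - mi_b) / total
    if variant == "table_scale":
        return 2.0 - abs(mi_a / total - 0.5)
    raise ValueError("variant must be 'printed' or 'table_scale'")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant image")
    return float((xc * yc).sum() / denom)


def corr(f: np.ndarray, a: np.ndarray, b: np.ndarray, mode: str = "mean") -> float:
    """Pearson correlation of F with the sources.

    mode="mean" (default) averages Corr(F,A) and Corr(F,B); mode="a" or
    "b" returns a single pairing.  Raises ValueError when an argument is
    constant (zero variance).
    """
    f_, a_, b_ = as_image(f), as_image(a), as_image(b)
    check_same_shape(f_, a_)
    check_same_shape(f_, b_)
    if mode == "a":
        return _pearson(f_, a_)
    if mode == "b":
        return _pearson(f_, b_)
    if mode == "mean":
        return 0.5 * (_pearson(f_, a_) + _pearson(f_, b_))
    raise ValueError("mode must be 'mean', 'a' or 'b'")


def sf(img: np.ndarray, divisor: str = "mn") -> float:
    """Spatial frequency sqrt(RF^2 + CF^2) of first differences.

    RF sums squared differences between vertically adjacent pixels, CF
    horizontally adjacent ones; sums run over valid pairs with the
    printed 1/(M*N) divisor by default (divisor="valid" available).
    """
    f = as_image(img)
    d_row = f[1:, :] - f[:-1, :]
    d_col = f[:, 1:] - f[:, :-1]
    if divisor == "mn":
        rf2 = (d_row * d_row).sum() / f.size
        cf2 = (d_col * d_col).sum() / f.size
    elif divisor == "valid":
        rf2 = (d_row * d_row).mean()
        cf2 = (d_col * d_col).mean()
    else:
        raise ValueError("divisor must be 'mn' or 'valid'")
    return float(np.sqrt(rf2 + cf2))


# QABF preservation-model constants (gradient strength / orientation
# sigmoids), the values in standard use in the fusion literature.  Each
# sigmoid is normalized by its value at perfect preservation so that an
# exact copy of a source scores 1.
_QG_GAMMA, _QG_K, _QG_SIGMA = 0.9994, -15.0, 0.5
_QA_GAMMA, _QA_K, _QA_SIGMA = 0.9879, -22.0, 0.8


def _sobel_strength_angle(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = sobel(img, axis=1, mode="reflect")
    sy = sobel(img, axis=0, mode="reflect")
    g = np.sqrt(sx * sx + sy * sy)
    alpha = np.arctan2(sy, np.where(sx == 0, 1e-30, sx))
    # orientation is line-like: fold into (-pi/2, pi/2]
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _sigmoid(x: np.ndarray, gamma: float, k: float, s: float) -> np.ndarray:
    raw = gamma / (1.0 + np.exp(k * (x - s)))
    peak = gamma / (1.0 + np.exp(k * (1.0 - s)))
    return raw / peak


def _edge_preservation(gs, als, gf, alf) -> np.ndarray:
    """Per-pixel preservation Q of a source's edges in the fused image."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gs > gf, gf / gs, np.where(gf > 0, gs / gf, 0.0))
    ratio = np.nan_to_num(ratio, nan=0.0)
    dalpha = 1.0 - np.abs(als - alf) / (np.pi / 2)
    qg = _sigmoid(ratio, _QG_GAMMA, _QG_K, _QG_SIGMA)
    qa = _sigmoid(np.clip(dalpha, 0.0, 1.0), _QA_GAMMA, _QA_K, _QA_SIGMA)
    return qg * qa


def qabf(f: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Edge-information preservation Q^{AB/F} in [0, 1].

    Sobel gradient strength and orientation of the fused image are
    compared against each source through sigmoidal preservation models;
    the per-source scores are averaged with the source edge strengths as
    weights.  1 means every source edge survives with strength and
    orientation intact; 0 means no edge information was transferred.
    """
    f_, a_, b_ = as_image(f), as_image(a), as_image(b)
    check_same_shape(f_, a_)
    check_same_shape(f_, b_)
    gf, alf = _sobel_strength_angle(f_)
    ga, ala = _sobel_strength_angle(a_)
    gb, alb = _sobel_strength_angle(b_)
    qaf = _edge_preservation(ga, ala, gf, alf)
    qbf = _edge_preservation(gb, alb, gf, alf)
    wa, wb = ga, gb
    denom = (wa + wb).sum()
    if denom == 0:
        return 0.0
    return float((qaf * wa + qbf * wb).sum() / denom)


def report(f: np.ndarray, a: np.ndarray, b: np.ndarray) -> MetricReport:
    """Assemble the full nine-score row with default variants."""
    return MetricReport(
        api=api(f),
        sd=sd(f),
        ag=ag(f),
        entropy=entropy(f),
        mif=mif(f, a, b),
        fs1=fs1(f, a, b),
        corr=corr(f, a, b),
        sf=sf(f),
        qabf=qabf(f, a, b),
    )
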