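"""Masked 3D gray-level co-occurrence texture analysis.

The co-occurrence matrix is accumulated over the 13 unique unit-offset
directions of the 26-neighbourhood (one per central-symmetry pair), with
both pair endpoints required to lie inside the mask. Each directional
count matrix is symmetrized by adding its transpose, the 13 matrices are
averaged, and the average is normalized to a joint probability matrix
p(i, j). Thirteen scalar Haralick statistics are then computed from p.

Because gray levels are assigned by per-ROI min-max quantization, every
feature is invariant under positive affine transforms of the input
intensities (v -> a*v + b, a > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .volume import RegionMaskSet, Volume

__all__ = [
    "DIRECTIONS_3D",
    "FEATURE_NAMES",
    "DegenerateRegionError",
    "QuantizedRegion",
    "CooccurrenceMatrix",
    "TextureFeatures",
    "quantize_roi",
    "build_glcm",
    "haralick_features",
    "texture_for_region",
]

#: the 13 unit-neighbourhood offsets up to central symmetry (distance-1
#: 26-neighbourhood; the other 13 are their negatives).
DIRECTIONS_3D = np.array(
    [
        (0, 0, 1),
        (0, 1, 0),
        (1, 0, 0),
        (0, 1, 1),
        (0, 1, -1),
        (1, 0, 1),
        (1, 0, -1),
        (1, 1, 0),
        (1, -1, 0),
        (1, 1, 1),
        (1, 1, -1),
        (1, -1, 1),
        (1, -1, -1),
    ],
    dtype=int,
)

FEATURE_NAMES = (
    "energy",
    "entropy",
    "correlation",
    "contrast",
    "variance",
    "sum_mean",
    "agreement",
    "cluster_shade",
    "cluster_tendency",
    "homogeneity",
    "max_probability",
    "inverse_variance",
    "dissimilarity",
)


class DegenerateRegionError(ValueError):
    """Raised when an ROI yields no valid co-occurrence pairs."""


@dataclass
class QuantizedRegion:
    """Integer gray levels 1..Q for in-mask voxels (0 marks out-of-mask)."""

    levels: np.ndarray
    Q: int
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        in_mask = self.levels[self.levels > 0]
        if in_mask.size and (in_mask.min() < 1 or in_mask.max() > self.Q):
            raise ValueError("in-mask levels must lie in [1, Q]")
        if self.vmax < self.vmin:
            raise ValueError("vmax must be >= vmin")


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric joint gray-level probability matrix."""

    p: np.ndarray
    n_pairs_per_direction: np.ndarray
    direction_set: np.ndarray = field(default_factory=lambda: DIRECTIONS_3D.copy())

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("p must be a square matrix")
        if np.any(self.p < 0):
            raise ValueError("p must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError(f"p must sum to 1 (got {self.p.sum():.9f})")

    @property
    def Q(self) -> int:
        return self.p.shape[0]


@dataclass
class TextureFeatures:
    """The 13 Haralick scalars plus bookkeeping for provenance."""

    energy: float
    entropy: float
    correlation: float
    contrast: float
    variance: float
    sum_mean: float
    agreement: float
    cluster_shade: float
    cluster_tendency: float
    homogeneity: float
    max_probability: float
    inverse_variance: float
    dissimilarity: float
    Q: int = 0
    n_voxels: int = 0
    n_pairs: int = 0
    degenerate: bool = False

    def to_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    @classmethod
    def missing(cls, Q: int = 0, n_voxels: int = 0) -> "TextureFeatures":
        return cls(
            *([float("nan")] * 13), Q=Q, n_voxels=n_voxels, n_pairs=0, degenerate=True
        )


def quantize_roi(v: Volume, mask: np.ndarray, Q: int = 32,
                 value_range: Optional[Tuple[float, float]] = None) -> QuantizedRegion:
    """Min-max quantize in-mask intensities to integer levels 1..Q.

    level(x) = min(Q, floor((v(x) - vmin) / (vmax - vmin) * Q) + 1),
    with vmin/vmax the in-mask extremes by default (``value_range``
    overrides them for fixed-range quantization). A constant ROI maps
    every voxel to level 1.
    """
    if Q < 2:
        raise ValueError(f"need at least 2 gray levels, got Q={Q}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != v.data.shape:
        raise ValueError("mask grid does not match volume grid")
    vals = v.data[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    if value_range is None:
        vmin, vmax = float(vals.min()), float(vals.max())
    else:
        vmin, vmax = map(float, value_range)
    levels = np.zeros(v.data.shape, dtype=np.int32)
    if vmax > vmin:
        lev = np.floor((vals - vmin) / (vmax - vmin) * Q).astype(np.int32) + 1
        np.clip(lev, 1, Q, out=lev)
    else:
        lev = np.ones(vals.shape, dtype=np.int32)
    levels[mask] = lev
    return QuantizedRegion(levels=levels, Q=Q, vmin=vmin, vmax=vmax)


def _offset_slices(shape, offset):
    src, dst = [], []
    for n, o in zip(shape, offset):
        o = int(o)
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def build_glcm(q: QuantizedRegion, distance: int = 1) -> CooccurrenceMatrix:
    """Accumulate the 13-direction symmetrized, averaged, normalized GLCM.

    Raises :class:`DegenerateRegionError` when no direction yields a
    valid in-mask voxel pair (for example a single-voxel ROI).
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    lv = q.levels
    Q = q.Q
    total = np.zeros((Q, Q), dtype=float)
    n_pairs = np.zeros(len(DIRECTIONS_3D), dtype=np.int64)
    for k, d in enumerate(DIRECTIONS_3D):
        off = d * distance
        if any(abs(int(o)) >= n for n, o in zip(lv.shape, off)):
            continue
        sl_a, sl_b = _offset_slices(lv.shape, off)
        a = lv[sl_a]
        b = lv[sl_b]
        valid = (a > 0) & (b > 0)
        av = a[valid].astype(np.int64) - 1
        bv = b[valid].astype(np.int64) - 1
        n_pairs[k] = av.size
        if av.size == 0:
            continue
        counts = np.bincount(av * Q + bv, minlength=Q * Q).reshape(Q, Q).astype(float)
        total += counts + counts.T
    if total.sum() == 0:
        raise DegenerateRegionError(
            "degenerate ROI: no valid co-occurrence pairs in any direction"
        )
    avg = total / len(DIRECTIONS_3D)
    return CooccurrenceMatrix(p=avg / avg.sum(), n_pairs_per_direction=n_pairs)


def haralick_features(
    m: CooccurrenceMatrix,
    homogeneity_form: str = "inverse_difference",
    cluster_tendency_exponent: int = 4,
) -> TextureFeatures:
    """Compute the 13 Haralick statistics from a normalized GLCM.

    With i, j in 1..Q and marginals px(i) = sum_j p(i, j),
    mu_x = sum_i i*px(i), sigma_x^2 = sum_i (i - mu_x)^2 px(i) (mu_y,
    sigma_y equal by symmetry):

    - energy          sum p^2
    - entropy         -sum_{p>0} p log2 p          (bits)
    - correlation     (sum ij p - mu_x mu_y) / (sigma_x sigma_y); 0 if sigma_x = 0
    - contrast        sum (i-j)^2 p
    - variance        sum (i - mu_x)^2 p
    - sum_mean        (1/2) sum (i+j) p
    - agreement       (Po - Pe) / (1 - Pe), Cohen's kappa of the diagonal,
                      Po = sum_i p(i,i), Pe = sum_i px(i) py(i);
                      1 if Pe = 1 and Po = 1, else 0 when Pe = 1
    - cluster_shade   sum (i + j - mu_x - mu_y)^3 p
    - cluster_tendency sum (i + j - mu_x - mu_y)^e p (e = 4, prominence)
    - homogeneity     sum p / (1 + |i-j|)   ("inverse difference"; the
                      squared-difference variant is a config switch)
    - max_probability max p
    - inverse_variance sum_{i != j} p / (i-j)^2
    - dissimilarity   sum |i-j| p
    """
    p = m.p
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("co-occurrence matrix is not normalized")
    Q = p.shape[0]
    i = np.arange(1, Q + 1, dtype=float)[:, None]
    j = np.arange(1, Q + 1, dtype=float)[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    levels = np.arange(1, Q + 1, dtype=float)
    mu_x = float(np.sum(levels * px))
    mu_y = float(np.sum(levels * py))
    sig_x = float(np.sqrt(np.sum((levels - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((levels - mu_y) ** 2 * py)))

    energy = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    if sig_x > 0 and sig_y > 0:
        correlation = float((np.sum(i * j * p) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 0.0
    diff = i - j
    contrast = float(np.sum(diff**2 * p))
    variance = float(np.sum((i - mu_x) ** 2 * p))
    sum_mean = float(0.5 * np.sum((i + j) * p))
    po = float(np.trace(p))
    pe = float(np.sum(px * py))
    if pe < 1.0 - 1e-12:
        agreement = (po - pe) / (1.0 - pe)
    else:
        agreement = 1.0 if po >= 1.0 - 1e-12 else 0.0
    dev = i + j - mu_x - mu_y
    cluster_shade = float(np.sum(dev**3 * p))
    cluster_tendency = float(np.sum(dev**cluster_tendency_exponent * p))
    if homogeneity_form == "inverse_difference":
        homogeneity = float(np.sum(p / (1.0 + np.abs(diff))))
    elif homogeneity_form == "inverse_difference_squared":
        homogeneity = float(np.sum(p / (1.0 + diff**2)))
    else:
        raise ValueError(f"unknown homogeneity form {homogeneity_form!r}")
    max_probability = float(p.max())
    inverse_variance = float(np.sum(p / np.where(diff == 0, np.inf, diff**2)))
    dissimilarity = float(np.sum(np.abs(diff) * p))

    return TextureFeatures(
        energy=energy,
        entropy=entropy,
        correlation=correlation,
        contrast=contrast,
        variance=variance,
        sum_mean=sum_mean,
        agreement=agreement,
        cluster_shade=cluster_shade,
        cluster_tendency=cluster_tendency,
        homogeneity=homogeneity,
        max_probability=max_probability,
        inverse_variance=inverse_variance,
        dissimilarity=dissimilarity,
        Q=Q,
        n_pairs=int(m.n_pairs_per_direction.sum()),
    )


def texture_for_region(
    v: Volume,
    masks: RegionMaskSet,
    region: str,
    Q: int = 32,
    distance: int = 1,
    homogeneity_form: str = "inverse_difference",
    cluster_tendency_exponent: int = 4,
    value_range: Optional[Tuple[float, float]] = None,
) -> TextureFeatures:
    """Quantize -> GLCM -> features for one named region.

    A degenerate ROI (no valid voxel pairs) yields a record of NaN
    features with ``degenerate=True`` rather than an exception, so a
    cohort run survives pathological subjects.
    """
    masks.check_grid(v)
    mask = masks[region]
    q = quantize_roi(v, mask, Q=Q, value_range=value_range)
    n_vox = int(np.count_nonzero(mask))
    try:
        glcm = build_glcm(q, distance=distance)
    except DegenerateRegionError:
        return TextureFeatures.missing(Q=Q, n_voxels=n_vox)
    feats = haralick_features(
        glcm,
        homogeneity_form=homogeneity_form,
        cluster_tendency_exponent=cluster_tendency_exponent,
    )
    feats.n_voxels = n_vox
    return feats
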