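"""Conventional striatal quantification.

Mean ROI uptake normalized to the occipital reference region (a
distribution-volume-ratio-like plain ratio), the |R-L| laterality
index, and the imaging-based more/less-affected side assignment used to
split bilateral structures before correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .volume import RegionMaskSet, Volume

__all__ = [
    "UptakeSummary",
    "mean_roi_uptake",
    "normalize_to_reference",
    "laterality_index",
    "assign_affected_sides",
]


@dataclass
class UptakeSummary:
    """Per-region raw means, reference-normalized ratios and side label."""

    mean_raw: Dict[str, float]
    mean_normalized: Dict[str, float] = field(default_factory=dict)
    reference_mean: Optional[float] = None
    more_affected_side: Optional[str] = None


def mean_roi_uptake(v: Volume, masks: RegionMaskSet) -> UptakeSummary:
    """Arithmetic mean of voxel intensities inside each named mask."""
    masks.check_grid(v)
    means = {}
    for name in masks.names():
        mask = masks[name]
        if not mask.any():
            raise ValueError(f"empty mask for region {name!r}")
        means[name] = float(v.data[mask].mean())
    return UptakeSummary(mean_raw=means)


def normalize_to_reference(
    summary: UptakeSummary, reference_region: str = "occipital"
) -> UptakeSummary:
    """Divide each region mean by the reference-region mean (plain ratio)."""
    if reference_region not in summary.mean_raw:
        raise KeyError(f"reference region {reference_region!r} missing from summary")
    ref = summary.mean_raw[reference_region]
    if ref <= 0:
        raise ValueError(f"reference mean must be positive, got {ref}")
    normalized = {name: m / ref for name, m in summary.mean_raw.items()}
    return UptakeSummary(
        mean_raw=dict(summary.mean_raw),
        mean_normalized=normalized,
        reference_mean=ref,
        more_affected_side=summary.more_affected_side,
    )


def laterality_index(right: float, left: float) -> float:
    """|R - L| / ((R + L) / 2); symmetric in its arguments, in [0, 2].

    Identical for raw and reference-normalized means, since the
    reference divides out of the ratio.
    """
    denom = (right + left) / 2.0
    if denom <= 0:
        raise ValueError(f"R + L must be positive, got R={right}, L={left}")
    return abs(right - left) / denom


def assign_affected_sides(summary: UptakeSummary) -> str:
    """Label the side with the lower normalized putamen mean as more affected.

    Ties break to "L"; the label is applied to the caudate of the same
    hemisphere downstream.
    """
    values = summary.mean_normalized or summary.mean_raw
    for region in ("putamen_L", "putamen_R"):
        if region not in values:
            raise KeyError(f"missing region {region!r} for side assignment")
    side = "L" if values["putamen_L"] <= values["putamen_R"] else "R"
    summary.more_affected_side = side
    return side
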