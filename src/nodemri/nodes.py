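"""Node-level ROI summarization, volumetry and RECIST 1.1 response rules.

The unit of analysis is a single metastatic cervical lymph node observed at
two timepoints (before and after induction chemotherapy).  Volume comes
from slice-wise planimetry (area x slice spacing); response categories come
from the short-axis diameter change: complete response (CR) on node
disappearance, partial response (PR) at a >= 30% diameter decrease,
progressive disease (PD) at a >= 20% increase, stable disease (SD)
otherwise.  CR and PR form the responding group (RG), SD and PD the
non-responding group (NRG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = [
    "NodeROI",
    "ResponseLabel",
    "roi_mean",
    "node_volume",
    "pct_change",
    "reduction_ratio",
    "classify_recist",
]


@dataclass(frozen=True)
class NodeROI:
    """Planimetric description of one node: per-slice areas plus geometry.

    Areas are in cm^2, thickness and gap in cm, so volumes come out in cm^3.
    """

    slice_areas: tuple[float, ...]
    slice_thickness: float
    interslice_gap: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.slice_areas, dtype=float)
        if np.any(a < 0):
            raise DataError("slice_areas must be non-negative")
        if self.slice_thickness <= 0:
            raise DataError("slice_thickness must be positive")
        if self.interslice_gap < 0:
            raise DataError("interslice_gap must be non-negative")
        object.__setattr__(self, "slice_areas", tuple(float(x) for x in a))


@dataclass(frozen=True)
class ResponseLabel:
    """RECIST category and the derived responder grouping."""

    category: str  # CR | PR | SD | PD
    group: str  # RG | NRG

    def __post_init__(self) -> None:
        if self.category not in ("CR", "PR", "SD", "PD"):
            raise DataError(f"unknown RECIST category {self.category!r}")
        expected = "RG" if self.category in ("CR", "PR") else "NRG"
        if self.group != expected:
            raise DataError(
                f"group {self.group!r} inconsistent with category {self.category!r}"
            )


def roi_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the image over in-mask voxels.

    Two-observer workflows average two ``roi_mean`` results upstream.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise DataError("image and mask shapes differ")
    if not mask.any():
        raise DataError("ROI mask is empty")
    return float(image[mask].mean())


def node_volume(roi: NodeROI) -> float:
    """Slice-summation volume: sum of area x (thickness + gap), in cm^3."""
    areas = np.asarray(roi.slice_areas, dtype=float)
    return float(areas.sum() * (roi.slice_thickness + roi.interslice_gap))


def pct_change(pre: float, post: float) -> float:
    """Signed percent change ``100 * (post - pre) / pre`` (positive = increase)."""
    if pre == 0:
        raise DataError("pct_change undefined for pre = 0")
    return 100.0 * (post - pre) / pre


def reduction_ratio(pre: float, post: float) -> float:
    """Percent reduction ``100 * (pre - post) / pre`` (positive = shrinkage).

    This is the sign convention under which a volume decrease prints as a
    positive reduction percentage; it equals ``-pct_change(pre, post)``.
    """
    if pre <= 0:
        raise DataError("reduction_ratio needs pre > 0")
    return 100.0 * (pre - post) / pre


def classify_recist(d_pre: float, d_post: float, strict: bool = False) -> ResponseLabel:
    """Classify one node from its pre/post short-axis diameters (mm).

    Percentage-only rules (default): CR on disappearance (d_post = 0), PR at
    a >= 30% decrease, PD at a >= 20% increase, SD otherwise.  With
    ``strict=True`` the full nodal RECIST 1.1 rules are applied on top: CR
    additionally when the short axis regresses below 10 mm, and PD
    additionally requires a >= 5 mm absolute increase.
    """
    if d_pre <= 0:
        raise DataError("d_pre must be positive")
    if d_post < 0:
        raise DataError("d_post must be non-negative")

    if d_post == 0 or (strict and d_post < 10.0):
        return ResponseLabel("CR", "RG")
    change = (d_post - d_pre) / d_pre
    if change <= -0.30:
        return ResponseLabel("PR", "RG")
    if change >= 0.20 and (not strict or d_post - d_pre >= 5.0):
        return ResponseLabel("PD", "NRG")
    return ResponseLabel("SD", "NRG")
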