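"""Perivascular-space and ventricle morphometry on axial MR slices.

Replicates the ImageJ-style workflow: binarize a T2 axial slice (fluid-filled
spaces are T2-bright), invert the display polarity so that the structures of
interest are the mask foreground, and compute relative area ratios — PVS area
over the brain area at the same level, ventricle area over the brain (or
cerebellum) area at its level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "AreaRatioResult",
    "RATIO_PAIRS",
    "ROI_LABELS",
    "RoiMask",
    "SliceImage",
    "binarize_invert",
    "invert_mask",
    "measure_area",
    "relative_area_ratio",
]

#: Region labels used throughout the morphometry workflow.
ROI_LABELS = (
    "frontal_PVS",
    "basal_ganglia_PVS",
    "lateral_ventricles",
    "fourth_ventricle",
    "brain_at_frontal_level",
    "basal_ganglia_total",
    "brain_at_ventricle_level",
    "cerebellum_at_fourth_level",
)

#: Numerator -> denominator pairs defining the four relative area ratios.
RATIO_PAIRS: dict[str, str] = {
    "frontal_PVS": "brain_at_frontal_level",
    "basal_ganglia_PVS": "basal_ganglia_total",
    "lateral_ventricles": "brain_at_ventricle_level",
    "fourth_ventricle": "cerebellum_at_fourth_level",
}


@dataclass(frozen=True)
class SliceImage:
    """A 2-D axial intensity slice with physical pixel spacing in mm."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("slice must be 2-D")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and non-negative")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest mask tied to a slice geometry.

    ``polarity`` records the binarize-and-invert convention: ``"inverted"``
    means the foreground is the T2-bright (fluid) class after inversion.
    """

    pixels: np.ndarray
    label: str
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    polarity: str = "inverted"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            if not np.isin(px, (0, 1)).all():
                raise ValueError("mask must be binary")
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")


def binarize_invert(
    image: SliceImage,
    method: str = "otsu",
    manual_threshold: float | None = None,
    min_size: int = 1,
    label: str = "foreground",
) -> RoiMask:
    """Binarize a slice and invert polarity so fluid structures are foreground.

    On T2 images the PVSs and ventricles are bright; binarization followed by
    inversion makes them the mask foreground.  The automatic threshold is
    Otsu's method; a ``manual_threshold`` overrides it.  Connected components
    smaller than ``min_size`` pixels are removed (``min_size=1`` disables the
    filter).

    Raises on a constant image under automatic thresholding, since no
    data-driven threshold exists.
    """
    px = image.pixels
    if manual_threshold is not None:
        thr = float(manual_threshold)
    elif method == "otsu":
        if np.ptp(px) == 0:
            raise ValueError("constant image: automatic thresholding is degenerate")
        thr = float(threshold_otsu(px))
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    mask = px > thr
    if min_size > 1:
        # drop connected components with fewer than min_size pixels
        mask = remove_small_objects(mask, max_size=min_size - 1)
    return RoiMask(pixels=mask, label=label, pixel_spacing=image.pixel_spacing,
                   polarity="inverted")


def invert_mask(mask: RoiMask) -> RoiMask:
    """Swap foreground and background (an involution)."""
    polarity = "raw" if mask.polarity == "inverted" else "inverted"
    return RoiMask(pixels=~mask.pixels, label=mask.label,
                   pixel_spacing=mask.pixel_spacing, polarity=polarity)


def measure_area(mask: RoiMask) -> float:
    """Foreground area in mm**2: pixel count times pixel area."""
    pixel_area = mask.pixel_spacing[0] * mask.pixel_spacing[1]
    return float(np.count_nonzero(mask.pixels)) * pixel_area


@dataclass(frozen=True)
class AreaRatioResult:
    """Relative area ratio of a structure to its reference region."""

    label: str
    numerator_area_mm2: float
    denominator_area_mm2: float

    @property
    def ratio(self) -> float:
        return self.numerator_area_mm2 / self.denominator_area_mm2


def relative_area_ratio(numerator: RoiMask, denominator: RoiMask) -> AreaRatioResult:
    """Ratio of the numerator structure area to the reference region area.

    Warns (masks not nested) when the numerator area exceeds the denominator
    area; raises on a zero-area denominator.
    """
    num_area = measure_area(numerator)
    den_area = measure_area(denominator)
    if den_area == 0:
        raise ValueError("denominator region has zero area")
    if num_area > den_area:
        warnings.warn(
            f"numerator area ({num_area:.1f} mm^2) exceeds denominator "
            f"({den_area:.1f} mm^2); masks are not nested",
            RuntimeWarning,
            stacklevel=2,
        )
    return AreaRatioResult(
        label=f"{numerator.label}/{denominator.label}",
        numerator_area_mm2=num_area,
        denominator_area_mm2=den_area,
    )
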