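"""Adherent-cell surface coverage from grayscale micrographs.

The adhesion readout is the ratio of cell-occupied area to total imaged
area, obtained by the classic three-step sequence: binarization (Otsu by
default, or a fixed threshold), noise removal (morphological opening plus
small-object rejection), and connected-component quantification, followed
by replicate statistics over several images of the same assay condition.

Coverage is dimensionless; no pixel-size calibration is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import filters, measure, morphology

__all__ = [
    "Micrograph",
    "BinaryMask",
    "CoverageResult",
    "ReplicateSummary",
    "binarize",
    "denoise",
    "quantify",
    "summarize_replicates",
    "analyze_micrograph",
]

MIN_IMAGE_SIDE = 64
DEFAULT_MIN_OBJECT_PX = 25
DEFAULT_OPENING_RADIUS = 1


@dataclass(frozen=True)
class Micrograph:
    """Single-channel grayscale micrograph with identifying labels."""

    pixels: np.ndarray
    image_id: str = "image"
    condition_id: str = "condition"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"{self.image_id}: expected a single-channel 2-D image")
        if min(px.shape) < MIN_IMAGE_SIDE:
            raise ValueError(
                f"{self.image_id}: image must be at least "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} px, got {px.shape}"
            )
        if not np.all(np.isfinite(px.astype(float))):
            raise ValueError(f"{self.image_id}: non-finite intensities")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class BinaryMask:
    """Foreground/background mask with the thresholding provenance."""

    pixels: np.ndarray
    threshold_used: float
    polarity: Literal["dark_cells", "light_cells"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))


@dataclass(frozen=True)
class CoverageResult:
    """Occupied-area/total-area for one image plus the object census."""

    coverage_fraction: float
    object_count: int
    object_areas_px: tuple[int, ...]
    image_id: str = "image"
    condition_id: str = "condition"

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction outside [0, 1]")


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- sample sd of coverage over replicate images of a condition."""

    mean_coverage: float
    sd_coverage: float
    n_images: int
    condition_id: str = "condition"
    single_image: bool = False


def binarize(
    image: Micrograph,
    method: Literal["otsu", "fixed"] = "otsu",
    polarity: Literal["dark_cells", "light_cells"] = "dark_cells",
    threshold: float | None = None,
    subtract_background: bool = False,
    background_window: int = 101,
) -> BinaryMask:
    """Convert a micrograph to a cell-candidate mask.

    ``dark_cells`` marks pixels *below* the threshold as foreground (cells
    darker than the field, the usual bright-field situation);
    ``light_cells`` marks pixels above it.  ``subtract_background``
    optionally removes a rolling-mean illumination estimate first (off by
    default).
    """
    px = image.pixels.astype(float)
    if subtract_background:
        from scipy.ndimage import uniform_filter

        px = px - uniform_filter(px, size=background_window) + px.mean()

    if method == "otsu":
        if np.ptp(px) == 0:
            raise ValueError(
                f"{image.image_id}: constant-intensity image, Otsu threshold degenerate"
            )
        thr = float(filters.threshold_otsu(px))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        lo, hi = float(px.min()), float(px.max())
        if not lo <= threshold <= hi:
            raise ValueError(
                f"fixed threshold {threshold} outside intensity range [{lo}, {hi}]"
            )
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")

    fg = px < thr if polarity == "dark_cells" else px > thr
    return BinaryMask(pixels=fg, threshold_used=thr, polarity=polarity)


def denoise(
    mask: BinaryMask,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
) -> BinaryMask:
    """Morphological opening then small-object removal.

    Degenerate parameters (0, 0) are the identity; the foreground pixel
    count never increases.
    """
    if min_object_px < 0 or opening_radius < 0:
        raise ValueError("cleanup parameters must be >= 0")
    px = mask.pixels
    if opening_radius > 0:
        px = morphology.opening(px, morphology.disk(opening_radius))
    if min_object_px > 0:
        # remove components strictly smaller than min_object_px, 8-connected
        px = morphology.remove_small_objects(
            px, max_size=min_object_px - 1, connectivity=2
        )
    return BinaryMask(pixels=px, threshold_used=mask.threshold_used, polarity=mask.polarity)


def quantify(mask: BinaryMask) -> CoverageResult:
    """Connected-component census (8-connectivity) and coverage fraction."""
    labels = measure.label(mask.pixels, connectivity=2)
    areas = tuple(
        int(n) for n in np.bincount(labels.ravel())[1:] if n > 0
    )
    total = mask.pixels.size
    return CoverageResult(
        coverage_fraction=float(np.count_nonzero(mask.pixels)) / total,
        object_count=len(areas),
        object_areas_px=areas,
    )


def summarize_replicates(results: Sequence[CoverageResult]) -> ReplicateSummary:
    """Mean and sample standard deviation (n-1) of replicate coverages.

    All results must share one condition; a single image yields sd 0 with
    the ``single_image`` flag set.
    """
    if len(results) == 0:
        raise ValueError("no coverage results to summarize")
    conditions = {r.condition_id for r in results}
    if len(conditions) != 1:
        raise ValueError(f"mixed condition_ids in replicate set: {sorted(conditions)}")
    cov = np.array([r.coverage_fraction for r in results])
    n = len(cov)
    return ReplicateSummary(
        mean_coverage=float(cov.mean()),
        sd_coverage=float(cov.std(ddof=1)) if n > 1 else 0.0,
        n_images=n,
        condition_id=conditions.pop(),
        single_image=(n == 1),
    )


def analyze_micrograph(
    image: Micrograph,
    method: Literal["otsu", "fixed"] = "otsu",
    polarity: Literal["dark_cells", "light_cells"] = "dark_cells",
    threshold: float | None = None,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
    subtract_background: bool = False,
) -> tuple[CoverageResult, BinaryMask]:
    """Full binarize -> denoise -> quantify pipeline for one micrograph."""
    mask = binarize(
        image, method=method, polarity=polarity, threshold=threshold,
        subtract_background=subtract_background,
    )
    mask = denoise(mask, min_object_px=min_object_px, opening_radius=opening_radius)
    result = quantify(mask)
    return (
        CoverageResult(
            coverage_fraction=result.coverage_fraction,
            object_count=result.object_count,
            object_areas_px=result.object_areas_px,
            image_id=image.image_id,
            condition_id=image.condition_id,
        ),
        mask,
    )
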