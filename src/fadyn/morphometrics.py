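"""Cell-shape descriptors: projected area, perimeter, circularity, aspect ratio.

Circularity is ``4*pi*A / p**2`` (1.0 for a perfect circle, lower for
elongated shapes) and the aspect ratio is the major/minor axis ratio of the
second-central-moment equivalent ellipse.

The perimeter of a rasterized shape depends strongly on how the boundary is
measured: counting pixel edges overestimates the length of diagonal
boundaries by up to ~sqrt(2), which biases circularity low by ~27% on disks,
and even a raw marching-squares polygon keeps ~4-6% of staircase excess on
curved boundaries.  The default estimator therefore smooths the mask with a
Gaussian whose width scales with the object size (sigma = sqrt(area)/100 px,
floored at 1 px) before tracing the half-level contour: staircase wiggle is
suppressed, corner rounding stays sub-percent for squares down to ~20 px,
and the measure is stable under resampling because the smoothing scales with
the shape.  A pixel-based mode (``mode="pixel"``) is kept for parity with
ImageJ-style measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure


@dataclass(frozen=True)
class CellGeometry:
    """Shape descriptors of one cell footprint (lengths in um)."""

    area: float
    perimeter: float
    circularity: float
    aspect_ratio: float
    major_axis: float
    minor_axis: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("area and perimeter must be > 0")
        if self.aspect_ratio < 1:
            raise ValueError(f"aspect_ratio must be >= 1, got {self.aspect_ratio}")


def projected_area(mask: np.ndarray, pixel_size: float) -> float:
    """Projected footprint area in um^2 (pixel count * pixel_size^2)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask has no projected area")
    return n * pixel_size**2


def perimeter(mask: np.ndarray, pixel_size: float, mode: str = "subpixel") -> float:
    """Boundary length in um; the sum over components for multi-part masks.

    ``mode="subpixel"`` traces marching-squares contours at the 0.5 level of
    the size-adaptively smoothed mask and sums their polygon lengths (falling
    back to the raw contour for objects too small to survive smoothing);
    ``mode="pixel"`` uses the pixel-boundary estimator (ImageJ-parity).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no perimeter")
    if mode == "pixel":
        return float(measure.perimeter(mask, neighborhood=4)) * pixel_size
    if mode != "subpixel":
        raise ValueError(f"unknown perimeter mode {mode!r}; use 'subpixel' or 'pixel'")
    sigma = max(1.0, np.sqrt(float(mask.sum())) / 100.0)
    pad = int(np.ceil(4 * sigma)) + 1
    smoothed = ndi.gaussian_filter(np.pad(mask.astype(float), pad), sigma)
    total = 0.0
    for contour in measure.find_contours(smoothed, 0.5):
        total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    if total == 0.0:  # tiny object erased by smoothing: raw contour
        for contour in measure.find_contours(np.pad(mask.astype(float), 1), 0.5):
            total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return total * pixel_size


def circularity(area: float, perimeter: float) -> float:
    """``4*pi*A / p**2``; reported raw (digitized shapes may exceed 1)."""
    if area <= 0 or perimeter <= 0:
        raise ValueError(f"area and perimeter must be > 0, got {area}, {perimeter}")
    return 4.0 * np.pi * area / perimeter**2


def _moment_axes(mask: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths (px) of the moment-equivalent ellipse.

    Uses central second moments with the standard +1/12 per-pixel variance
    term, matching the ellipse-of-inertia convention.
    """
    rows, cols = np.nonzero(mask)
    n = rows.size
    r = rows - rows.mean()
    c = cols - cols.mean()
    mrr = (r @ r) / n + 1 / 12
    mcc = (c @ c) / n + 1 / 12
    mrc = (r @ c) / n
    common = np.sqrt((mrr - mcc) ** 2 + 4 * mrc**2)
    l1 = (mrr + mcc + common) / 2
    l2 = (mrr + mcc - common) / 2
    return 4.0 * np.sqrt(max(l1, 0.0)), 4.0 * np.sqrt(max(l2, 0.0))


def aspect_ratio(mask: np.ndarray) -> float:
    """Major/minor axis ratio of the equivalent ellipse (>= 1).

    The per-pixel 1/12 variance term regularizes collinear masks: a 1-px-wide
    line has the minor axis of its pixel footprint (about 1.15 px) rather
    than zero, so the ratio stays finite and reflects the drawn shape.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("aspect ratio needs >= 2 foreground pixels")
    major, minor = _moment_axes(mask)
    return float(major / minor)


def cell_geometry(
    mask: np.ndarray, pixel_size: float, perimeter_mode: str = "subpixel"
) -> CellGeometry:
    """All shape descriptors of one footprint in one record."""
    a = projected_area(mask, pixel_size)
    p = perimeter(mask, pixel_size, mode=perimeter_mode)
    major_px, minor_px = _moment_axes(np.asarray(mask, dtype=bool))
    return CellGeometry(
        area=a,
        perimeter=p,
        circularity=circularity(a, p),
        aspect_ratio=aspect_ratio(mask),
        major_axis=major_px * pixel_size,
        minor_axis=minor_px * pixel_size,
    )
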