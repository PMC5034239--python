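"""Background subtraction, thresholding and object labelling.

Raw fluorescence channels are converted to binary masks after background
subtraction; masks are labelled into objects with a minimum-area filter.
Within a batch (a time series, or all conditions of one experiment) a single
numeric threshold is reused, mirroring common ImageJ practice of applying
the same threshold to every image of an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu


def round_half_away(x: float) -> int:
    """Round half away from zero (so 2.5 um -> 3 px, not banker's 2)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def subtract_background(
    image: np.ndarray, ball_radius: float, pixel_size: float | None = None
) -> np.ndarray:
    """Rolling-ball-style background subtraction via morphological opening.

    ``ball_radius`` is in um when ``pixel_size`` is given, else in px.  The
    background estimate is a grayscale opening with a disk of that radius;
    the result ``image - opening`` is non-negative everywhere.
    """
    if ball_radius <= 0:
        raise ValueError(f"ball_radius must be > 0, got {ball_radius}")
    radius_px = round_half_away(ball_radius / pixel_size) if pixel_size else round_half_away(ball_radius)
    if radius_px < 1:
        raise ValueError(
            f"ball_radius {ball_radius} converts to {radius_px} px (< 1 px); increase it"
        )
    image = np.asarray(image, dtype=np.float64)
    opened = morphology.opening(image, morphology.disk(radius_px))
    return image - opened


def resolve_threshold(image: np.ndarray, method: str | float) -> float:
    """Resolve a threshold specification against an image.

    ``method`` is ``"otsu"``, ``"fixed:VALUE"``, ``"robust:K"`` (median +
    K times the MAD-based noise scale — suited to sparse puncta, where Otsu
    would split the background noise), or a plain number.  Otsu on a
    constant image is ill-posed and raises.
    """
    if isinstance(method, (int, float)):
        return float(method)
    if method == "otsu":
        image = np.asarray(image)
        if np.ptp(image) == 0:
            raise ValueError(
                "otsu thresholding needs >= 2 distinct intensity values; "
                "use a fixed threshold ('fixed:VALUE') for constant images"
            )
        return float(threshold_otsu(image))
    if method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    if method.startswith("robust:"):
        k = float(method.split(":", 1)[1])
        image = np.asarray(image)
        med = float(np.median(image))
        mad = float(np.median(np.abs(image - med)))
        return med + k * 1.4826 * mad
    raise ValueError(
        f"unknown threshold method {method!r}; use 'otsu', 'fixed:VALUE' or 'robust:K'"
    )


def threshold_mask(image: np.ndarray, method: str | float = "otsu") -> tuple[np.ndarray, float]:
    """Binarize one image; returns ``(mask, threshold_used)``.

    The mask is ``image > threshold``.
    """
    thr = resolve_threshold(image, method)
    return np.asarray(image) > thr, thr


def threshold_series(
    frames: np.ndarray | Sequence[np.ndarray], method: str | float = "otsu"
) -> tuple[np.ndarray, float]:
    """Binarize a series with one shared threshold.

    The threshold is resolved on the *first* frame (Otsu by default) and then
    applied fixed to every frame, honouring the same-threshold-per-experiment
    rule.  Returns ``(masks, threshold_used)``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"expected a (T, Y, X) series, got shape {frames.shape}")
    thr = resolve_threshold(frames[0], method)
    return frames > thr, thr


@dataclass
class LabelMap:
    """Labelled objects of one frame with provenance.

    ``labels`` holds consecutive integer labels 1..N on a background of 0.
    """

    labels: np.ndarray
    pixel_size: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def areas_px(self) -> np.ndarray:
        """Pixel area of each label, index 0 = label 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)[1:]

    def areas_um2(self) -> np.ndarray:
        return self.areas_px() * self.pixel_size**2

    def centroids_um(self) -> np.ndarray:
        """(N, 2) array of (x, y) centroids in um."""
        n = self.n_labels
        if n == 0:
            return np.zeros((0, 2))
        com = ndi.center_of_mass(np.ones_like(self.labels), self.labels, index=np.arange(1, n + 1))
        com = np.asarray(com)  # (row, col)
        return np.stack([com[:, 1], com[:, 0]], axis=1) * self.pixel_size

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


def label_regions(
    mask: np.ndarray,
    min_area: float = 0.0,
    pixel_size: float = 1.0,
    connectivity: int = 2,
    provenance: dict | None = None,
) -> LabelMap:
    """8-connected components with a minimum-area filter.

    ``min_area`` is in um^2 (with the given ``pixel_size``); components below
    it are removed and the survivors relabelled consecutively 1..N in scan
    order.  An empty mask yields an empty map, not an error.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = ndi.generate_binary_structure(2, connectivity)
    labels, n = ndi.label(mask, structure=structure)
    min_area_px = min_area / pixel_size**2
    if n and min_area_px > 0:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        keep = areas >= min_area_px
        keep[0] = False
        mapping = np.zeros(n + 1, dtype=np.int32)
        mapping[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = mapping[labels]
    prov = dict(provenance or {})
    prov.setdefault("min_area_um2", min_area)
    prov.setdefault("min_area_px", min_area_px)
    prov.setdefault("connectivity", connectivity)
    return LabelMap(labels=labels.astype(np.int32), pixel_size=pixel_size, provenance=prov)


def cell_mask(
    image: np.ndarray,
    method: str | float = "otsu",
    fill_holes: bool = True,
) -> np.ndarray:
    """Segment the cell footprint: threshold, keep the largest component,
    optionally fill holes.

    Raises if nothing survives thresholding.
    """
    mask, thr = threshold_mask(image, method)
    if not mask.any():
        raise ValueError(f"no foreground after thresholding at {thr}; cannot build a cell mask")
    labels, n = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2))
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(sizes)))
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    return mask
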