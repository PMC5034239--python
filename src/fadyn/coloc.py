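"""Differential triple colocalization by binary-mask algebra.

Three thresholded channels are decomposed into the seven exclusive
combinations (A-only, B-only, C-only, AB, AC, BC, ABC).  Within
neighbourhoods around reference (e.g. vinculin-positive) adhesions — a
0.8 um dilation of each adhesion and/or a 5 x 4 um crop centred on it — the
integrated density of each combination is expressed as a fraction of each
channel's in-region total, so the four combinations containing a channel sum
exactly to that channel's total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .prep import LabelMap, round_half_away


@dataclass
class Neighborhood:
    """Analysis regions around one reference adhesion."""

    label: int
    centroid_px: tuple[float, float]  # (x, y) px
    dilated: np.ndarray  # reference object grown by the dilation distance
    crop: np.ndarray  # rectangular crop mask
    crop_clipped: bool  # crop ran past the image border


@dataclass
class NeighborhoodSet:
    """Per-reference region masks plus the realized pixel parameters."""

    regions: list[Neighborhood]
    dilation_distance: float  # um
    dilation_radius_px: int  # realized radius
    crop_size: tuple[float, float]  # um (long, short)
    pixel_size: float
    overlapping: bool  # any two regions share pixels


def build_neighborhoods(
    reference: LabelMap,
    dilation_distance: float = 0.8,
    crop_size: tuple[float, float] = (5.0, 4.0),
    pixel_size: float | None = None,
    crop_aligned: bool = True,
) -> NeighborhoodSet:
    """Build per-adhesion analysis regions.

    Each reference object is dilated by a disk of radius ``dilation_distance``
    (um, realized radius in px recorded), and additionally a
    ``crop_size[0] x crop_size[1]`` um rectangle is centred on the object
    centroid — long axis along the object's principal axis when
    ``crop_aligned`` (else image-axis aligned).  Overlapping neighbourhoods
    are processed independently; shared pixels count in both and the set is
    flagged.
    """
    px = pixel_size if pixel_size is not None else reference.pixel_size
    if reference.n_labels < 1:
        raise ValueError("need at least one reference object")
    radius_px = round_half_away(dilation_distance / px)
    footprint = morphology.disk(radius_px)
    labels = reference.labels
    rows_img, cols_img = labels.shape
    half_long = crop_size[0] / 2 / px
    half_short = crop_size[1] / 2 / px

    regions: list[Neighborhood] = []
    for lab in range(1, reference.n_labels + 1):
        obj = labels == lab
        rr, cc = np.nonzero(obj)
        crow, ccol = rr.mean(), cc.mean()
        dilated = ndi.binary_dilation(obj, structure=footprint)

        if crop_aligned and rr.size > 1:
            r = rr - crow
            c = cc - ccol
            cov = np.array([[c @ c, c @ r], [c @ r, r @ r]]) / rr.size
            evals, evecs = np.linalg.eigh(cov)
            ux, uy = evecs[:, int(np.argmax(evals))]  # (x, y) of the major axis
        else:
            ux, uy = 1.0, 0.0
        yy, xx = np.mgrid[0:rows_img, 0:cols_img]
        dx = xx - ccol
        dy = yy - crow
        s = dx * ux + dy * uy
        q = -dx * uy + dy * ux
        # half-open [-half, half) so the realized window is exactly size/px
        crop = (s >= -half_long) & (s < half_long) & (q >= -half_short) & (q < half_short)
        # clipped when the ideal rectangle would extend past the border
        corners_s = np.array([half_long, half_long, -half_long, -half_long])
        corners_q = np.array([half_short, -half_short, half_short, -half_short])
        cx = ccol + corners_s * ux - corners_q * uy
        cy = crow + corners_s * uy + corners_q * ux
        clipped = bool(
            (cx < -0.5).any()
            or (cy < -0.5).any()
            or (cx > cols_img - 0.5).any()
            or (cy > rows_img - 0.5).any()
        )
        regions.append(
            Neighborhood(
                label=lab,
                centroid_px=(float(ccol), float(crow)),
                dilated=dilated,
                crop=crop,
                crop_clipped=clipped,
            )
        )

    overlapping = False
    for a, b in itertools.combinations(regions, 2):
        if (a.dilated & b.dilated).any() or (a.crop & b.crop).any():
            overlapping = True
            break
    return NeighborhoodSet(
        regions=regions,
        dilation_distance=dilation_distance,
        dilation_radius_px=radius_px,
        crop_size=crop_size,
        pixel_size=px,
        overlapping=overlapping,
    )


# Exclusive combinations in canonical order; the name lists the channels
# present, all others absent.
COMBO_NAMES = ("A", "B", "C", "AB", "AC", "BC", "ABC")


def exclusive_combinations(
    mask_a: np.ndarray, mask_b: np.ndarray, mask_c: np.ndarray
) -> dict[str, np.ndarray]:
    """Decompose three masks into the 7 disjoint exclusive combinations.

    The returned masks partition the union of the inputs: ``"AB"`` contains
    pixels in A and B but not C, and so on.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    c = np.asarray(mask_c, dtype=bool)
    if not (a.shape == b.shape == c.shape):
        raise ValueError(f"mask shapes differ: {a.shape}, {b.shape}, {c.shape}")
    return {
        "A": a & ~b & ~c,
        "B": ~a & b & ~c,
        "C": ~a & ~b & c,
        "AB": a & b & ~c,
        "AC": a & ~b & c,
        "BC": ~a & b & c,
        "ABC": a & b & c,
    }


def integrated_density(image: np.ndarray, mask: np.ndarray, background: float = 0.0) -> float | int:
    """Sum of (background-subtracted) intensities over a mask.

    Integer images with zero background sum in exact integer arithmetic.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if background == 0.0 and np.issubdtype(image.dtype, np.integer):
        return int(image[mask].sum(dtype=np.int64))
    return float((image[mask] - background).sum())


@dataclass
class ColocalizationReport:
    """Per-region and summary colocalization fractions.

    ``per_region`` is tidy: one row per (region, channel, combination) with
    pixel count, integrated density and the fraction of the channel's
    in-region total.  ``summary`` averages fractions over regions with a
    defined total ("averaged and plotted").
    """

    per_region: pd.DataFrame
    summary: pd.DataFrame
    region_kind: str = "dilated"
    flags: dict = field(default_factory=dict)


def coloc_fractions(
    images: Mapping[str, np.ndarray],
    masks: Mapping[str, np.ndarray],
    regions: Sequence[np.ndarray] | NeighborhoodSet | None = None,
    region_kind: str = "dilated",
    background: float | Mapping[str, float] = 0.0,
    mode: str = "density",
) -> ColocalizationReport:
    """Differential colocalization fractions for three channels.

    Parameters
    ----------
    images, masks
        Same three keys each (channel names); masks are the thresholded
        channels.  ``mode="density"`` weights by (background-subtracted)
        intensity, ``mode="pixels"`` counts mask pixels.
    regions
        Region masks to analyse, a :class:`NeighborhoodSet` (using its
        ``region_kind`` regions), or None for one whole-image region.

    For each channel X and region, the four exclusive combinations containing
    X are expressed as fractions of X's in-region masked total; regions where
    a channel has zero total get missing fractions and a flag.
    """
    names = list(images)
    if len(names) != 3 or set(names) != set(masks):
        raise ValueError("need the same three channel names in images and masks")
    shapes = {np.asarray(images[n]).shape for n in names} | {np.asarray(masks[n]).shape for n in names}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: {sorted(shapes)}")

    if isinstance(regions, NeighborhoodSet):
        region_masks = [getattr(r, region_kind) for r in regions.regions]
        region_ids = [r.label for r in regions.regions]
    elif regions is None:
        region_masks = [np.ones(next(iter(shapes)), dtype=bool)]
        region_ids = [0]
    else:
        region_masks = [np.asarray(r, dtype=bool) for r in regions]
        region_ids = list(range(len(region_masks)))

    bg = {n: (background[n] if isinstance(background, Mapping) else background) for n in names}
    combos = exclusive_combinations(masks[names[0]], masks[names[1]], masks[names[2]])
    letter_of = dict(zip(names, "ABC"))

    rows = []
    undefined: list[tuple[int, str]] = []
    for rid, region in zip(region_ids, region_masks):
        for channel in names:
            letter = letter_of[channel]
            img = np.asarray(images[channel])
            chan_mask = np.asarray(masks[channel], dtype=bool)
            my_combos = [c for c in COMBO_NAMES if letter in c]
            densities = {}
            pixels = {}
            for combo in my_combos:
                m = combos[combo] & region
                pixels[combo] = int(m.sum())
                densities[combo] = (
                    float(pixels[combo]) if mode == "pixels"
                    else float(integrated_density(img, m, background=bg[channel]))
                )
            total = (
                float((chan_mask & region).sum()) if mode == "pixels"
                else float(integrated_density(img, chan_mask & region, background=bg[channel]))
            )
            if total == 0:
                undefined.append((rid, channel))
            for combo in my_combos:
                rows.append(
                    {
                        "region": rid,
                        "channel": channel,
                        "combination": combo,
                        "pixels": pixels[combo],
                        "density": densities[combo],
                        "channel_total": total,
                        "fraction": densities[combo] / total if total != 0 else np.nan,
                    }
                )

    per_region = pd.DataFrame(
        rows,
        columns=["region", "channel", "combination", "pixels", "density", "channel_total", "fraction"],
    )
    summary = (
        per_region.groupby(["channel", "combination"], sort=False)["fraction"]
        .mean()
        .reset_index()
        .rename(columns={"fraction": "mean_fraction"})
    )
    return ColocalizationReport(
        per_region=per_region,
        summary=summary,
        region_kind=region_kind if regions is not None else "whole-image",
        flags={"undefined_channel_regions": undefined},
    )
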