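"""Canned study conditions: simulation scenarios plus their recovery analyses.

These functions pin down the synthetic acquisition conditions used for
validation — a 60-frame, 1 frame/min adhesion time-lapse over a large
spread cell; a triple-colocalization field with prescribed overlap
fractions; vesicle fields with and without peripheral bias — and run the
corresponding measurement chain, returning recovered-vs-truth tables.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import coloc as _coloc
from . import dynamics as _dyn
from . import partition as _part
from . import prep as _prep
from .simulate import (
    AcquisitionSpec,
    OverlapSpec,
    VesicleFieldSpec,
    apply_imaging,
    edge_distance_um,
    sample_kinetics,
    simulate_adhesion_timelapse,
    simulate_cell_mask,
    simulate_coloc_triad,
    simulate_vesicle_field,
    substream,
    _render_ribbon,
    _render_spot,
)
from .stack import ImageStack

#: Acquisition for turnover studies: 1 h at 1 frame/min, 0.16 um/px, 1-px PSF.
TURNOVER_ACQ = AcquisitionSpec(
    n_frames=60,
    frame_interval=1.0,
    pixel_size=0.16,
    image_shape=(688, 960),
    psf_sigma=0.16,
    background_level=10.0,
    poisson_scale=0.0,
    read_noise_sigma=0.0,
)

#: Shot-noise scale giving peak SNR ~ 10 for 100-intensity objects on a
#: background of 10 (SNR = S*sqrt(k)/sqrt(S+B)).
SNR10_POISSON_SCALE = 1.1


def turnover_cell(acq: AcquisitionSpec = TURNOVER_ACQ) -> np.ndarray:
    """The spread-cell footprint used by the turnover studies (72 x 50 um
    semi-axes, large enough for 30 well-separated peripheral adhesions)."""
    return simulate_cell_mask(
        acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (72.0, 50.0)}
    )


def turnover_condition(
    seed: int,
    n_adhesions: int = 30,
    disassembly_scale: float = 1.0,
    acq: AcquisitionSpec = TURNOVER_ACQ,
    noisy: bool = False,
):
    """Simulate one experimental condition of the turnover assay.

    ``disassembly_scale`` rescales every adhesion's disassembly speed
    (0.5 emulates a disassembly-specific knockdown); assembly draws are
    untouched, so conditions sharing a seed differ *only* in disassembly.
    """
    if noisy:
        acq = AcquisitionSpec(
            n_frames=acq.n_frames,
            frame_interval=acq.frame_interval,
            pixel_size=acq.pixel_size,
            image_shape=acq.image_shape,
            psf_sigma=acq.psf_sigma,
            background_level=acq.background_level,
            poisson_scale=SNR10_POISSON_SCALE,
            read_noise_sigma=2.0,
        )
    cell = turnover_cell(acq)
    kin = sample_kinetics(
        cell, acq.pixel_size, n_adhesions, seed, disassembly_scale=disassembly_scale
    )
    return simulate_adhesion_timelapse(cell, kin, acq, seed=seed)


def recover_turnover(
    stack: ImageStack,
    cell_mask: np.ndarray,
    smooth_window: int = 1,
    threshold: str | float = "robust:8",
):
    """Run the full measurement chain on a simulated turnover stack.

    Detection uses the robust noise-based threshold (sparse bright ribbons on
    a dominant background make Otsu split the background noise instead).
    """
    return _dyn.analyze_turnover(
        stack,
        channel="adhesion",
        cell_mask=cell_mask,
        smooth_window=smooth_window,
        threshold=threshold,
    )


def match_tracks_to_truth(
    per_track: pd.DataFrame, truth_adhesions: pd.DataFrame, max_distance: float = 3.0
) -> pd.DataFrame:
    """Pair recovered tracks with ground-truth adhesions by position.

    Each truth adhesion is matched to the nearest recovered track centre
    (tracks are well separated by construction); pairs farther apart than
    ``max_distance`` um stay unmatched.  Returns truth columns merged with
    the matched track's metrics; unmatched truth rows have NaN metrics.
    """
    # expected ribbon midpoint: halfway between the final tips
    u = np.stack(
        [np.cos(truth_adhesions["axis_angle"]), np.sin(truth_adhesions["axis_angle"])], axis=1
    )
    ext = truth_adhesions["v_assembly"] * (
        truth_adhesions["t_halt_start"] - truth_adhesions["t_appear"]
    )
    mid_s = (ext.to_numpy() - 1.5) / 2  # initial_length default 1.5 um
    mid = (
        np.stack([truth_adhesions["anchor_x"], truth_adhesions["anchor_y"]], axis=1)
        + mid_s[:, None] * u
    )
    out_rows = []
    centers = per_track[["center_x", "center_y"]].to_numpy() if len(per_track) else np.zeros((0, 2))
    for i, row in truth_adhesions.reset_index(drop=True).iterrows():
        rec: dict = dict(row)
        if len(centers):
            d = np.hypot(centers[:, 0] - mid[i, 0], centers[:, 1] - mid[i, 1])
            j = int(np.argmin(d))
            if d[j] <= max_distance:
                for col in per_track.columns:
                    rec[f"rec_{col}"] = per_track.iloc[j][col]
                rec["match_distance"] = float(d[j])
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def turnover_recovery_study(
    seed: int, n_adhesions: int = 30, disassembly_scale: float = 1.0, noisy: bool = False
) -> pd.DataFrame:
    """Simulate + recover + match one condition; returns the matched table."""
    stack, truth = turnover_condition(
        seed, n_adhesions=n_adhesions, disassembly_scale=disassembly_scale, noisy=noisy
    )
    result = recover_turnover(stack, truth.cell_mask, smooth_window=3 if noisy else 1)
    return match_tracks_to_truth(result.per_track, truth.adhesions)


def condition_comparison(
    seeds=(1, 2, 3), n_adhesions: int = 30, disassembly_scale: float = 0.5
) -> pd.DataFrame:
    """Control vs disassembly-suppressed condition over several replicates.

    Returns one row per (seed, condition) with the mean recovered assembly
    rate, disassembly rate and lifespan (censoring-agnostic means, as every
    adhesion of both conditions shares the same appearance schedule).
    """
    rows = []
    for seed in seeds:
        for name, scale in (("control", 1.0), ("silenced", disassembly_scale)):
            matched = turnover_recovery_study(seed, n_adhesions, disassembly_scale=scale)
            rows.append(
                {
                    "seed": seed,
                    "condition": name,
                    "mean_assembly_rate": matched["rec_assembly_rate"].mean(),
                    "mean_disassembly_rate": matched["rec_disassembly_rate"].mean(),
                    "mean_lifespan": matched["rec_lifespan"].mean(),
                    "n_matched": int(matched["rec_track_id"].notna().sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# colocalization recovery
# ---------------------------------------------------------------------------

#: Exclusive-overlap design for channel A: half exclusive, 0.3 shared with B,
#: 0.2 shared with both — on top of realistic B-only/C-only/BC context.
COLOC_COUNTS = {"A": 500, "AB": 300, "ABC": 200, "B": 250, "C": 200, "BC": 120}


def coloc_recovery_study(seed: int, snr10: bool = True) -> dict:
    """Simulate a triad with known overlap fractions and recover them.

    Channels are thresholded (Otsu, one threshold per channel), decomposed
    into exclusive combinations, and channel-A integrated-density fractions
    are compared with the design.  Returns truth and recovered fractions.
    """
    acq = AcquisitionSpec(
        n_frames=1,
        pixel_size=0.16,
        image_shape=(320, 440),
        psf_sigma=0.0,
        background_level=10.0,
        poisson_scale=SNR10_POISSON_SCALE if snr10 else 0.0,
        read_noise_sigma=2.0 if snr10 else 0.0,
    )
    cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (32.0, 22.0)})
    spec = OverlapSpec(counts=COLOC_COUNTS)
    stack, truth = simulate_coloc_triad(cell, spec, acq, seed=seed)

    images = {name: stack.frame(0, name) for name in "ABC"}
    masks = {}
    backgrounds = {}
    for name in "ABC":
        m, _ = _prep.threshold_mask(images[name], "otsu")
        masks[name] = m
        backgrounds[name] = float(np.median(images[name][~m]))
    report = _coloc.coloc_fractions(images, masks, regions=None, background=backgrounds)

    total_a = sum(truth.overlap_counts[c] for c in ("A", "AB", "AC", "ABC"))
    truth_fracs = {c: truth.overlap_counts[c] / total_a for c in ("A", "AB", "AC", "ABC")}
    rec = report.per_region
    rec_a = rec[rec["channel"] == "A"].set_index("combination")["fraction"]
    return {
        "truth": truth_fracs,
        "recovered": {c: float(rec_a[c]) for c in ("A", "AB", "AC", "ABC")},
        "report": report,
    }


# ---------------------------------------------------------------------------
# vesicle peripheral enrichment
# ---------------------------------------------------------------------------


def vesicle_enrichment_study(seed: int, peripheral_bias: float, n_vesicles: int = 200) -> dict:
    """Simulate a vesicle field and measure its peripheral enrichment.

    Thresholds the vesicle channel, partitions the cell at the 10-um band and
    reports the peripheral normalized area together with the truth fraction
    of vesicle centres in the band.
    """
    acq = AcquisitionSpec(
        n_frames=1,
        pixel_size=0.16,
        image_shape=(400, 540),
        psf_sigma=0.16,
        background_level=10.0,
        poisson_scale=SNR10_POISSON_SCALE,
        read_noise_sigma=2.0,
    )
    cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (38.0, 27.0)})
    spec = VesicleFieldSpec(
        n_vesicles=n_vesicles, peripheral_bias=peripheral_bias, diffusion_step=0.0
    )
    stack, truth = simulate_vesicle_field(cell, spec, acq, seed=seed)
    # sparse puncta on a noisy background: robust noise-based threshold
    mask, _ = _prep.threshold_mask(stack.frame(0), "robust:8")
    part = _part.partition_cell(cell, band_width=10.0, pixel_size=acq.pixel_size)
    sig = _part.peripheral_signal(mask & cell, part)
    frame0 = truth.vesicles[truth.vesicles["frame"] == 0]
    return {
        "peripheral_normalized": sig.peripheral_normalized,
        "peripheral_fraction": sig.peripheral / sig.total if sig.total else np.nan,
        "truth_band_fraction": float(frame0["in_band"].mean()),
        "rab_area_ratio": _part.rab_area_ratio(mask, cell),
        "partition": part,
    }


def per_fa_enrichment_study(seed: int, intensity_ratio: float = 2.0, n_per_group: int = 8) -> dict:
    """Vesicle signal at peripheral vs central adhesions with a known ratio.

    Builds a cell with ``n_per_group`` identical adhesions in the peripheral
    band and ``n_per_group`` in the central region, places one identical
    vesicle spot at each adhesion with ``intensity_ratio``-fold brighter
    spots peripherally, and recovers the per-adhesion neighbourhood-density
    ratio through the 0.8-um-neighbourhood / 10-um-partition chain.
    """
    acq = AcquisitionSpec(
        n_frames=1,
        pixel_size=0.16,
        image_shape=(400, 540),
        psf_sigma=0.16,
        background_level=10.0,
        poisson_scale=SNR10_POISSON_SCALE,
        read_noise_sigma=2.0,
    )
    px = acq.pixel_size
    cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (38.0, 27.0)})
    d_um = edge_distance_um(cell, px)
    rows, cols = np.nonzero(cell)
    crow, ccol = rows.mean(), cols.mean()

    def point_at_edge_distance(theta: float, target: float) -> tuple[float, float]:
        # walk outward from the centroid until the edge distance drops to target
        best = None
        for rad in np.arange(1.0, 60.0, 0.25):
            c = ccol + rad / px * np.cos(theta)
            r = crow + rad / px * np.sin(theta)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < cell.shape[0] and 0 <= ci < cell.shape[1]) or not cell[ri, ci]:
                break
            if d_um[ri, ci] >= target:
                best = (c * px, r * px)
        if best is None:
            raise ValueError("no point at requested edge distance")
        return best

    angles = np.linspace(0, 2 * np.pi, n_per_group, endpoint=False)
    peripheral_pts = [point_at_edge_distance(a, 4.0) for a in angles]  # last point with d >= 4
    central_pts = [point_at_edge_distance(a + np.pi / n_per_group, 14.0) for a in angles]
    # refine: peripheral = outermost point still >= 4 um from the edge
    refined = []
    for a in angles:
        pts = []
        for rad in np.arange(1.0, 60.0, 0.25):
            c = ccol + rad / px * np.cos(a)
            r = crow + rad / px * np.sin(a)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < cell.shape[0] and 0 <= ci < cell.shape[1]) or not cell[ri, ci]:
                break
            if 3.0 <= d_um[ri, ci] <= 5.0:
                pts.append((c * px, r * px))
        refined.append(pts[len(pts) // 2] if pts else peripheral_pts[0])
    peripheral_pts = refined

    fa_signal = np.zeros(cell.shape)
    rab_signal = np.zeros(cell.shape)
    base = 100.0
    for group, pts, amp in (
        ("peripheral", peripheral_pts, base * intensity_ratio),
        ("central", central_pts, base),
    ):
        for x, y in pts:
            _render_ribbon(fa_signal, (x / px, y / px), np.array([1.0, 0.0]), -1.0 / px, 1.0 / px, 0.8 / px, 100.0)
            _render_spot(rab_signal, x / px, y / px, 0.3 / px, amp)

    fa_img = apply_imaging(fa_signal, acq, substream(seed, "fa"))
    rab_img = apply_imaging(rab_signal, acq, substream(seed, "rab"))

    fa_mask, _ = _prep.threshold_mask(fa_img, "otsu")
    labels = _prep.label_regions(fa_mask, min_area=0.2, pixel_size=px)
    hoods = _coloc.build_neighborhoods(labels, dilation_distance=0.8, pixel_size=px)
    part = _part.partition_cell(cell, band_width=10.0, pixel_size=px)
    bg = float(np.median(rab_img[~cell]))
    groups = _part.per_fa_rab_intensity(rab_img, hoods, part, background=bg)
    ratio = float(np.mean(groups["peripheral"]) / np.mean(groups["central"]))
    return {
        "ratio": ratio,
        "n_peripheral": len(groups["peripheral"]),
        "n_central": len(groups["central"]),
        "groups": groups,
    }
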