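"""Focal-adhesion detection, tracking, kymographs and turnover metrics.

The measurement chain mirrors the classic kymograph protocol:

1. detect adhesions per frame on the thresholded adhesion channel;
2. link detections over time by footprint overlap into tracks;
3. fit each track's growth axis and trace a 10-um line along it, oriented
   so the positive direction points toward the nearest cell edge (distal);
4. build the position x time kymograph along that line;
5. locate the distal and proximal adhesion tips per frame at half-maximum
   above background, with sub-pixel interpolation of the crossing;
6. segment the tip series into assembly, disassembly and halt events and
   report per-adhesion rates (dD/dT, um/min), halt time, lifespan and event
   counts.

The assembly rate is the extension speed of the distal tip toward the cell
edge; the disassembly rate is the retraction speed of the proximal tip; the
halt time is the period without either kind of event; the lifespan is the
time the adhesion is visible within the acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .prep import LabelMap, label_regions, threshold_series
from .stack import ImageStack


# ---------------------------------------------------------------------------
# detection and tracking
# ---------------------------------------------------------------------------


def detect_adhesions(
    frame: np.ndarray,
    threshold: str | float = "otsu",
    min_area: float = 0.0,
    pixel_size: float = 1.0,
) -> LabelMap:
    """Label adhesions in one frame of the adhesion channel."""
    from .prep import threshold_mask

    mask, thr = threshold_mask(frame, threshold)
    return label_regions(
        mask, min_area=min_area, pixel_size=pixel_size, provenance={"threshold": thr}
    )


@dataclass
class AdhesionTrack:
    """One adhesion followed through time.

    ``footprints`` holds flat pixel indices into a frame of ``shape`` for
    each entry of ``frames`` (strictly increasing; short gaps bridged by
    linking are simply absent).
    """

    track_id: int
    shape: tuple[int, int]
    pixel_size: float
    frames: list[int] = field(default_factory=list)
    footprints: list[np.ndarray] = field(default_factory=list)
    centroids_um: list[tuple[float, float]] = field(default_factory=list)
    censored_start: bool = False
    censored_end: bool = False

    @property
    def first_frame(self) -> int:
        return self.frames[0]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def union_mask(self) -> np.ndarray:
        """Union of all per-frame footprints."""
        mask = np.zeros(self.shape, dtype=bool)
        for fp in self.footprints:
            mask.ravel()[fp] = True
        return mask


def track_adhesions(
    label_maps: list[LabelMap] | list[np.ndarray],
    pixel_size: float | None = None,
    max_gap: int = 1,
) -> list[AdhesionTrack]:
    """Link per-frame detections into tracks by footprint overlap.

    Greedy frame-to-frame assignment by maximal overlap fraction (overlap
    pixels over the smaller footprint), ties broken by smaller centroid
    distance, then smaller label.  Unmatched objects start new tracks; a
    track missing for at most ``max_gap`` frames may re-match afterwards.
    Tracks touching the first/last frame are flagged censored.
    """
    if len(label_maps) < 2:
        raise ValueError("tracking needs at least 2 frames")
    arrays = []
    for lm in label_maps:
        if isinstance(lm, LabelMap):
            arrays.append(lm.labels)
            if pixel_size is None:
                pixel_size = lm.pixel_size
        else:
            arrays.append(np.asarray(lm))
    px = pixel_size or 1.0
    shape = arrays[0].shape
    n_total_frames = len(arrays)

    tracks: list[AdhesionTrack] = []
    active: list[AdhesionTrack] = []

    for t, labels in enumerate(arrays):
        n = int(labels.max())
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        if n:
            com = ndi.center_of_mass(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            centroids = np.asarray(com)  # (row, col)
        else:
            centroids = np.zeros((0, 2))

        candidates = []
        for ti, track in enumerate(active):
            fp = track.footprints[-1]
            hits = np.bincount(labels.ravel()[fp], minlength=n + 1)
            prev_area = fp.size
            cx_prev, cy_prev = track.centroids_um[-1]
            for lab in np.nonzero(hits[1:])[0] + 1:
                frac = hits[lab] / min(prev_area, areas[lab])
                cr, cc = centroids[lab - 1]
                dist = np.hypot(cc * px - cx_prev, cr * px - cy_prev)
                candidates.append((-frac, dist, lab, ti))
        candidates.sort()

        used_tracks: set[int] = set()
        used_labels: set[int] = set()
        for neg_frac, dist, lab, ti in candidates:
            if ti in used_tracks or lab in used_labels:
                continue
            used_tracks.add(ti)
            used_labels.add(lab)
            track = active[ti]
            track.frames.append(t)
            track.footprints.append(np.flatnonzero(labels == lab))
            cr, cc = centroids[lab - 1]
            track.centroids_um.append((cc * px, cr * px))

        for lab in range(1, n + 1):
            if lab in used_labels:
                continue
            track = AdhesionTrack(track_id=len(tracks), shape=shape, pixel_size=px)
            track.frames.append(t)
            track.footprints.append(np.flatnonzero(labels == lab))
            cr, cc = centroids[lab - 1]
            track.centroids_um.append((cc * px, cr * px))
            tracks.append(track)
            active.append(track)

        active = [tr for tr in active if t - tr.last_frame <= max_gap]

    for track in tracks:
        track.censored_start = track.first_frame == 0
        track.censored_end = track.last_frame == n_total_frames - 1
    return tracks


# ---------------------------------------------------------------------------
# growth axis and kymograph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthAxis:
    """A 10-um measurement line along an adhesion's growth axis.

    The unit vector points distally (toward the nearest cell-edge point);
    positions along the line run from the proximal end ``p0`` to the distal
    end ``p1``.
    """

    center_um: tuple[float, float]
    angle: float  # radians of the distal direction
    unit: tuple[float, float]
    p0_um: tuple[float, float]  # proximal end
    p1_um: tuple[float, float]  # distal end
    length_um: float
    clipped: bool
    fallback: bool  # True when the displacement fallback oriented the axis


def growth_axis(
    track: AdhesionTrack,
    cell_mask: np.ndarray,
    pixel_size: float | None = None,
    length_um: float = 10.0,
    isotropy_tol: float = 1.15,
) -> GrowthAxis:
    """Fit the growth axis of a track and trace the measurement line.

    The axis is the principal axis of the union of the track's footprints;
    near-isotropic unions (moment ratio below ``isotropy_tol``) fall back to
    the net centroid displacement.  The sign is chosen so the positive
    direction points toward the nearest cell edge, and the line of
    ``length_um`` is centred on the union centroid; endpoints outside the
    image are flagged clipped.
    """
    if track.n_frames < 2:
        raise ValueError("growth axis needs a track of >= 2 frames")
    px = pixel_size or track.pixel_size
    union = track.union_mask()
    rows, cols = np.nonzero(union)
    crow, ccol = rows.mean(), cols.mean()
    r = rows - crow
    c = cols - ccol
    cov = np.array([[c @ c, c @ r], [c @ r, r @ r]]) / rows.size
    evals, evecs = np.linalg.eigh(cov)
    fallback = False
    if evals[0] <= 0 or evals[1] / max(evals[0], 1e-12) < isotropy_tol:
        dx = track.centroids_um[-1][0] - track.centroids_um[0][0]
        dy = track.centroids_um[-1][1] - track.centroids_um[0][1]
        norm = np.hypot(dx, dy)
        if norm < 0.25 * px:
            raise ValueError(
                "growth axis undefined: isotropic footprint and no net displacement"
            )
        ux, uy = dx / norm, dy / norm
        fallback = True
    else:
        ux, uy = evecs[:, 1]  # (x, y) of the major axis

    # orient distally: +u must point toward the nearest cell-edge point
    # (feature transform; a finite-difference probe of the distance map is
    # ambiguous near the cell's medial axis)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    _, (near_r, near_c) = ndi.distance_transform_edt(cell_mask, return_indices=True)
    ri = int(np.clip(round(crow), 0, cell_mask.shape[0] - 1))
    ci = int(np.clip(round(ccol), 0, cell_mask.shape[1] - 1))
    vx = float(near_c[ri, ci] - ccol)
    vy = float(near_r[ri, ci] - crow)
    if vx * ux + vy * uy < 0:
        ux, uy = -ux, -uy

    center = (ccol * px, crow * px)
    half = length_um / 2
    p0 = (center[0] - half * ux, center[1] - half * uy)
    p1 = (center[0] + half * ux, center[1] + half * uy)
    h, w = union.shape
    clipped = any(
        not (0 <= x <= (w - 1) * px and 0 <= y <= (h - 1) * px) for x, y in (p0, p1)
    )
    return GrowthAxis(
        center_um=center,
        angle=float(np.arctan2(uy, ux)),
        unit=(float(ux), float(uy)),
        p0_um=p0,
        p1_um=p1,
        length_um=length_um,
        clipped=clipped,
        fallback=fallback,
    )


@dataclass
class KymographRecord:
    """Position x time intensity matrix sampled along a growth-axis line.

    ``matrix[i, t]`` is the width-averaged intensity at ``positions_um[i]``
    along the line (0 at the proximal end, increasing distally) in frame t.
    """

    matrix: np.ndarray
    positions_um: np.ndarray
    axis: GrowthAxis
    sample_step_um: float
    width_avg: int
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


def extract_kymograph(
    frames: np.ndarray | ImageStack,
    axis: GrowthAxis,
    pixel_size: float | None = None,
    width_avg: int = 3,
    channel: int | str = 0,
) -> KymographRecord:
    """Sample the kymograph along a line, one column per frame.

    The line is sampled at 1-px steps by bilinear interpolation and averaged
    over ``width_avg`` perpendicular 1-px-spaced parallel lines.
    """
    if isinstance(frames, ImageStack):
        px = frames.pixel_size
        dt = frames.frame_interval
        data = frames.channel(channel)
    else:
        if pixel_size is None:
            raise ValueError("pixel_size required when passing a bare array")
        px = pixel_size
        dt = 1.0
        data = np.asarray(frames)
    if axis.length_um <= 0:
        raise ValueError("zero-length line")
    n_samples = int(round(axis.length_um / px)) + 1
    s = np.arange(n_samples)  # px steps along the line
    ux, uy = axis.unit
    x0, y0 = axis.p0_um
    offsets = np.arange(width_avg) - (width_avg - 1) / 2
    cols = x0 / px + s[:, None] * ux + offsets[None, :] * (-uy)
    rows_ = y0 / px + s[:, None] * uy + offsets[None, :] * ux
    coords = np.stack([rows_.ravel(), cols.ravel()])
    matrix = np.empty((n_samples, data.shape[0]))
    for t in range(data.shape[0]):
        vals = ndi.map_coordinates(data[t].astype(np.float64), coords, order=1, mode="nearest")
        matrix[:, t] = vals.reshape(n_samples, width_avg).mean(axis=1)
    return KymographRecord(
        matrix=matrix,
        positions_um=s * px,
        axis=axis,
        sample_step_um=px,
        width_avg=width_avg,
        frame_interval=dt,
    )


def locate_tips(
    kymo: KymographRecord,
    background_level: float = 0.0,
    min_contrast: float = 0.0,
    frame_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame distal and proximal tip positions (um along the line).

    In each column the adhesion extent is the contiguous run of samples at or
    above background + 50% of (column max - background); run edges are
    refined to sub-pixel accuracy by linear interpolation of the half-max
    crossing.  The distal tip is the cell-edge-side (high-position) end.
    Columns without signal (max - background <= min_contrast) are NaN; when
    several runs exist the one nearest the previous frame's tips is kept
    (first frame: the brightest run).  ``frame_range`` restricts the search
    to ``[first, last]`` inclusive.
    """
    n_pos, n_frames = kymo.matrix.shape
    distal = np.full(n_frames, np.nan)
    proximal = np.full(n_frames, np.nan)
    pos = kymo.positions_um
    lo, hi = (0, n_frames - 1) if frame_range is None else frame_range
    prev_center: float | None = None

    for t in range(max(lo, 0), min(hi, n_frames - 1) + 1):
        col = kymo.matrix[:, t]
        peak = float(col.max())
        if peak - background_level <= min_contrast:
            prev_center = None
            continue
        level = background_level + 0.5 * (peak - background_level)
        above = col >= level
        # contiguous runs of samples above the half-max level
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = list(np.flatnonzero(above & ~np.roll(above, 1)))
        if above[0]:
            starts = [0] + [s for s in starts if s != 0]
        runs = []
        for s0 in starts:
            s1 = s0
            while s1 + 1 < n_pos and above[s1 + 1]:
                s1 += 1
            runs.append((s0, s1))
        del edges
        if not runs:
            continue
        if len(runs) == 1 or prev_center is None:
            if len(runs) > 1:
                run = max(runs, key=lambda r: float(col[r[0] : r[1] + 1].sum()))
            else:
                run = runs[0]
        else:
            run = min(runs, key=lambda r: abs((pos[r[0]] + pos[r[1]]) / 2 - prev_center))
        s0, s1 = run
        # sub-pixel crossings
        if s0 == 0:
            p_lo = pos[0]
        else:
            f = (level - col[s0 - 1]) / (col[s0] - col[s0 - 1])
            p_lo = pos[s0 - 1] + f * kymo.sample_step_um
        if s1 == n_pos - 1:
            p_hi = pos[-1]
        else:
            f = (col[s1] - level) / (col[s1] - col[s1 + 1])
            p_hi = pos[s1] + f * kymo.sample_step_um
        proximal[t] = p_lo
        distal[t] = p_hi
        prev_center = (p_lo + p_hi) / 2

    if np.all(np.isnan(distal)):
        raise ValueError("no adhesion on line: every kymograph column is at background")
    return distal, proximal


# ---------------------------------------------------------------------------
# event segmentation and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnoverEvent:
    """One assembly, disassembly or halt interval of a tip series."""

    kind: str  # "assembly" | "disassembly" | "halt"
    t_start: float  # min
    t_end: float  # min
    delta_d: float  # um (0 for halt)
    rate: float  # um/min, dD/dT over the whole segment (0 for halt)

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("event must have t_end > t_start")


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return series
    out = series.copy()
    half = window // 2
    n = len(series)
    for i in range(n):
        seg = series[max(0, i - half) : min(n, i + half + 1)]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = np.median(seg)
    return out


def segment_events(
    distal: np.ndarray,
    proximal: np.ndarray,
    times: np.ndarray,
    min_rate: float = 0.05,
    min_duration: int = 3,
    smooth_window: int = 1,
) -> list[TurnoverEvent]:
    """Split tip series into assembly, disassembly and halt events.

    Frame-to-frame intervals are classified by tip motion (threshold at half
    of ``min_rate * dt`` for noise immunity; distal advance takes precedence
    over proximal advance so classes stay exclusive), then merged into
    maximal runs.  A moving run spanning >= ``min_duration`` frames with mean
    rate >= ``min_rate`` becomes an assembly/disassembly event with rate
    dD/dT over the whole segment; shorter or slower runs count as halt.
    Events never span frames with undefined tips.
    """
    raw_distal = np.asarray(distal, dtype=float)
    raw_proximal = np.asarray(proximal, dtype=float)
    times = np.asarray(times, dtype=float)
    if smooth_window > 1:
        distal = _smooth(raw_distal, smooth_window)
        proximal = _smooth(raw_proximal, smooth_window)
    else:
        distal, proximal = raw_distal, raw_proximal
    valid = np.isfinite(distal) & np.isfinite(proximal)
    events: list[TurnoverEvent] = []

    i = 0
    n = len(times)
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1]:
            j += 1
        sl = slice(i, j + 1)
        events.extend(
            _segment_block(
                distal[sl], proximal[sl], raw_distal[sl], raw_proximal[sl],
                times[sl], min_rate, min_duration,
            )
        )
        i = j + 1
    return events


def _event_rate(series: np.ndarray, times: np.ndarray, k: int, m: int) -> float:
    """dD/dT over a segment: least-squares slope of the raw tip positions
    (equals the endpoint ratio for noiseless linear motion, unbiased under
    jitter)."""
    t = times[k : m + 2]
    y = series[k : m + 2]
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return float("nan")
    t, y = t[ok], y[ok]
    if t.size == 2:
        return float((y[1] - y[0]) / (t[1] - t[0]))
    return float(np.polyfit(t, y, 1)[0])


def _segment_block(
    distal: np.ndarray,
    proximal: np.ndarray,
    raw_distal: np.ndarray,
    raw_proximal: np.ndarray,
    times: np.ndarray,
    min_rate: float,
    min_duration: int,
) -> list[TurnoverEvent]:
    n = len(times)
    if n < 2:
        return []
    cls = np.empty(n - 1, dtype="<U1")
    for k in range(n - 1):
        dt = times[k + 1] - times[k]
        thr = 0.5 * min_rate * dt
        if distal[k + 1] - distal[k] >= thr:
            cls[k] = "a"
        elif proximal[k + 1] - proximal[k] >= thr:
            cls[k] = "d"
        else:
            cls[k] = "h"

    # demote moving runs that are too short or too slow to halt
    changed = True
    while changed:
        changed = False
        k = 0
        while k < n - 1:
            m = k
            while m + 1 < n - 1 and cls[m + 1] == cls[k]:
                m += 1
            if cls[k] in "ad":
                series = distal if cls[k] == "a" else proximal
                span_frames = m - k + 2  # frames covered by intervals k..m
                delta = series[m + 1] - series[k]
                rate = delta / (times[m + 1] - times[k])
                if span_frames < min_duration or rate < min_rate:
                    cls[k : m + 1] = "h"
                    changed = True
            k = m + 1

    out: list[TurnoverEvent] = []
    k = 0
    while k < n - 1:
        m = k
        while m + 1 < n - 1 and cls[m + 1] == cls[k]:
            m += 1
        t0, t1 = times[k], times[m + 1]
        if cls[k] == "a":
            rate = _event_rate(raw_distal, times, k, m)
            out.append(TurnoverEvent("assembly", t0, t1, float(rate * (t1 - t0)), rate))
        elif cls[k] == "d":
            rate = _event_rate(raw_proximal, times, k, m)
            out.append(TurnoverEvent("disassembly", t0, t1, float(rate * (t1 - t0)), rate))
        else:
            out.append(TurnoverEvent("halt", t0, t1, 0.0, 0.0))
        k = m + 1
    return out


@dataclass
class AdhesionDynamics:
    """Per-adhesion turnover metrics.

    Rates are means over the corresponding events (NaN when no event of that
    kind occurred — missing, never 0).  Event counts are reported raw and
    normalized to a 60-min observation.
    """

    track_id: int
    assembly_rate: float  # um/min
    disassembly_rate: float  # um/min
    halt_time: float  # min, summed over halt intervals
    lifespan: float  # min, capped at the acquisition duration
    n_assembly: int
    n_disassembly: int
    n_halt: int
    assembly_per_60min: float
    disassembly_per_60min: float
    halt_per_60min: float
    assembly_time: float
    disassembly_time: float
    undefined_time: float
    censored_start: bool
    censored_end: bool


def turnover_metrics(
    events: list[TurnoverEvent],
    track: AdhesionTrack,
    acq_duration: float,
    frame_interval: float = 1.0,
) -> AdhesionDynamics:
    """Aggregate events into per-adhesion turnover metrics.

    Lifespan is ``(last_frame - first_frame + 1) * frame_interval`` capped at
    the acquisition duration; halt time sums all halt intervals; the
    undefined-tip time is the remainder, so assembly + disassembly + halt +
    undefined time equals the within-track interval time exactly.
    """
    if not events and track.n_frames == 0:
        raise ValueError("empty event list and empty track")
    a_rates = [e.rate for e in events if e.kind == "assembly"]
    d_rates = [e.rate for e in events if e.kind == "disassembly"]
    a_time = sum(e.t_end - e.t_start for e in events if e.kind == "assembly")
    d_time = sum(e.t_end - e.t_start for e in events if e.kind == "disassembly")
    h_time = sum(e.t_end - e.t_start for e in events if e.kind == "halt")
    lifespan = min((track.last_frame - track.first_frame + 1) * frame_interval, acq_duration)
    observed_intervals = (track.last_frame - track.first_frame) * frame_interval
    undefined = max(observed_intervals - a_time - d_time - h_time, 0.0)
    observed = max(lifespan, frame_interval)
    n_a = len(a_rates)
    n_d = len(d_rates)
    n_h = sum(1 for e in events if e.kind == "halt")
    return AdhesionDynamics(
        track_id=track.track_id,
        assembly_rate=float(np.mean(a_rates)) if a_rates else float("nan"),
        disassembly_rate=float(np.mean(d_rates)) if d_rates else float("nan"),
        halt_time=float(h_time),
        lifespan=float(lifespan),
        n_assembly=n_a,
        n_disassembly=n_d,
        n_halt=n_h,
        assembly_per_60min=n_a / observed * 60.0,
        disassembly_per_60min=n_d / observed * 60.0,
        halt_per_60min=n_h / observed * 60.0,
        assembly_time=float(a_time),
        disassembly_time=float(d_time),
        undefined_time=float(undefined),
        censored_start=track.censored_start,
        censored_end=track.censored_end,
    )


# ---------------------------------------------------------------------------
# density and peripheral-region measures
# ---------------------------------------------------------------------------


def adhesion_density(
    label_map: LabelMap, cell_mask: np.ndarray, pixel_size: float | None = None
) -> tuple[int, float, float]:
    """(count, count per um^2, adhesion-area fraction) on one frame.

    Per the source protocol these densities are measured on the first image
    of a time series.
    """
    px = pixel_size or label_map.pixel_size
    cell_mask = np.asarray(cell_mask, dtype=bool)
    cell_px = int(cell_mask.sum())
    if cell_px == 0:
        raise ValueError("cell mask is empty")
    count = label_map.n_labels
    fa_px = int(((label_map.labels > 0) & cell_mask).sum())
    return count, count / (cell_px * px**2), fa_px / cell_px


def peripheral_adhesion_fraction(
    adhesion_mask: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size: float,
    region_size: tuple[float, float] = (20.0, 10.0),
    anchor_um: tuple[float, float] | None = None,
) -> float:
    """Adhesion coverage of a 20 x 10 um region at the cell edge.

    The rectangle is placed with its long edge tangent to the cell boundary
    at ``anchor_um`` (a boundary point; when omitted, the boundary point
    farthest from the cell centroid — the protrusion apex — is used) and
    extends inward by the short side.  The fraction is adhesion-positive
    pixels over region pixels inside the cell.
    """
    adhesion_mask = np.asarray(adhesion_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    rows, cols = np.nonzero(cell_mask)
    crow, ccol = rows.mean(), cols.mean()
    boundary = cell_mask & ~ndi.binary_erosion(cell_mask)
    brows, bcols = np.nonzero(boundary)
    if anchor_um is None:
        d2 = (brows - crow) ** 2 + (bcols - ccol) ** 2
        k = int(np.argmax(d2))
        arow, acol = float(brows[k]), float(bcols[k])
    else:
        acol, arow = anchor_um[0] / pixel_size, anchor_um[1] / pixel_size
    # outward normal approximated by the centroid-to-anchor direction
    nx, ny = acol - ccol, arow - crow
    norm = np.hypot(nx, ny)
    if norm == 0:
        raise ValueError("anchor coincides with the cell centroid")
    nx, ny = nx / norm, ny / norm
    tx, ty = -ny, nx
    long_half = region_size[0] / 2 / pixel_size
    short_half = region_size[1] / 2 / pixel_size
    cx = acol - short_half * nx
    cy = arow - short_half * ny
    yy, xx = np.mgrid[0 : cell_mask.shape[0], 0 : cell_mask.shape[1]]
    s = (xx - cx) * tx + (yy - cy) * ty
    q = (xx - cx) * nx + (yy - cy) * ny
    region = (np.abs(s) <= long_half) & (np.abs(q) <= short_half)
    inside = region & cell_mask
    if not inside.any():
        raise ValueError("peripheral region lies entirely outside the cell")
    return int((adhesion_mask & inside).sum()) / int(inside.sum())


# ---------------------------------------------------------------------------
# end-to-end per-stack analysis
# ---------------------------------------------------------------------------


@dataclass
class DynamicsResult:
    """Everything the turnover analysis of one stack produces."""

    tracks: list[AdhesionTrack]
    per_track: pd.DataFrame
    events: pd.DataFrame
    kymographs: dict[int, KymographRecord]
    cell_mask: np.ndarray
    threshold: float
    background_level: float


def analyze_turnover(
    stack: ImageStack,
    channel: int | str = "adhesion",
    cell_mask: np.ndarray | None = None,
    threshold: str | float = "otsu",
    min_area: float = 0.15,
    max_gap: int = 1,
    line_length: float = 10.0,
    width_avg: int = 3,
    min_rate: float = 0.05,
    min_duration: int = 3,
    min_track_frames: int = 3,
    smooth_window: int = 1,
    min_contrast: float | None = None,
) -> DynamicsResult:
    """Run the full turnover chain on an adhesion-channel stack.

    Thresholds the whole series with one shared threshold, tracks adhesions,
    and measures each track of at least ``min_track_frames`` frames along its
    10-um growth-axis line.  The background level for tip finding is the
    median intensity outside the cell footprint; ``min_contrast`` defaults to
    five times the robust noise scale estimated from the same pixels.
    """
    frames = stack.channel(channel)
    masks, thr = threshold_series(frames, threshold)
    if cell_mask is None:
        from .prep import cell_mask as _cell_mask

        cell_mask = _cell_mask(ndi.gaussian_filter(stack.max_projection(channel), 2.0))
    cell_mask = np.asarray(cell_mask, dtype=bool)
    outside = frames[0][~cell_mask]
    background = float(np.median(outside)) if outside.size else 0.0
    if min_contrast is None:
        mad = float(np.median(np.abs(outside - background))) if outside.size else 0.0
        min_contrast = 5.0 * 1.4826 * mad

    label_maps = [
        label_regions(m, min_area=min_area, pixel_size=stack.pixel_size,
                      provenance={"threshold": thr, "frame": t})
        for t, m in enumerate(masks)
    ]
    tracks = track_adhesions(label_maps, pixel_size=stack.pixel_size, max_gap=max_gap)

    metric_rows = []
    event_rows = []
    kymos: dict[int, KymographRecord] = {}
    for track in tracks:
        if track.n_frames < min_track_frames:
            continue
        try:
            axis = growth_axis(track, cell_mask, pixel_size=stack.pixel_size, length_um=line_length)
        except ValueError:
            continue
        kymo = extract_kymograph(stack, axis, width_avg=width_avg, channel=channel)
        try:
            distal, proximal = locate_tips(
                kymo,
                background_level=background,
                min_contrast=min_contrast,
                frame_range=(track.first_frame, track.last_frame),
            )
        except ValueError:
            continue
        events = segment_events(
            distal,
            proximal,
            stack.times,
            min_rate=min_rate,
            min_duration=min_duration,
            smooth_window=smooth_window,
        )
        dyn = turnover_metrics(
            events,
            track,
            acq_duration=stack.n_frames * stack.frame_interval,
            frame_interval=stack.frame_interval,
        )
        kymos[track.track_id] = kymo
        cx, cy = axis.center_um
        metric_rows.append(
            {
                "track_id": track.track_id,
                "center_x": cx,
                "center_y": cy,
                "axis_angle": axis.angle,
                "axis_clipped": axis.clipped,
                "first_frame": track.first_frame,
                "last_frame": track.last_frame,
                "lifespan_frames": track.last_frame - track.first_frame + 1,
                "assembly_rate": dyn.assembly_rate,
                "disassembly_rate": dyn.disassembly_rate,
                "halt_time": dyn.halt_time,
                "lifespan": dyn.lifespan,
                "n_assembly": dyn.n_assembly,
                "n_disassembly": dyn.n_disassembly,
                "n_halt": dyn.n_halt,
                "assembly_per_60min": dyn.assembly_per_60min,
                "disassembly_per_60min": dyn.disassembly_per_60min,
                "halt_per_60min": dyn.halt_per_60min,
                "censored_start": dyn.censored_start,
                "censored_end": dyn.censored_end,
            }
        )
        for e in events:
            event_rows.append(
                {
                    "track_id": track.track_id,
                    "kind": e.kind,
                    "t_start": e.t_start,
                    "t_end": e.t_end,
                    "delta_d": e.delta_d,
                    "rate": e.rate,
                }
            )

    per_track = pd.DataFrame(
        metric_rows,
        columns=[
            "track_id", "center_x", "center_y", "axis_angle", "axis_clipped",
            "first_frame", "last_frame", "lifespan_frames", "assembly_rate",
            "disassembly_rate", "halt_time", "lifespan", "n_assembly",
            "n_disassembly", "n_halt", "assembly_per_60min",
            "disassembly_per_60min", "halt_per_60min", "censored_start",
            "censored_end",
        ],
    )
    events_df = pd.DataFrame(
        event_rows, columns=["track_id", "kind", "t_start", "t_end", "delta_d", "rate"]
    )
    return DynamicsResult(
        tracks=tracks,
        per_track=per_track,
        events=events_df,
        kymographs=kymos,
        cell_mask=cell_mask,
        threshold=thr,
        background_level=background,
    )
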