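# Methods

This note documents the models, algorithms and parameter choices behind
`fadyn`, in the order data flows through the pipeline.  Units are
micrometres and minutes throughout; all randomness derives from one explicit
seed through per-object substreams (`SeedSequence(seed, object-key)`), so
adding an object to a scene never reshuffles the draws of existing objects.

## Synthetic footage

### Adhesion time-lapse

A focal adhesion is modelled as a rectangular ribbon of width `width`
(default 0.8 µm) along a fixed growth axis whose distal direction points
toward the nearest cell-edge point (focal adhesions extend toward the
protruding edge).  Its kinematics are piecewise linear:

- at `t_appear` the ribbon exists with length `initial_length` (1.5 µm);
  `anchor` is the distal-tip position at appearance;
- the **distal tip** extends at `v_assembly` µm/min until `t_halt_start`:
  `distal(t) = anchor + v_assembly * min(t − t_appear, t_halt_start − t_appear)`;
- between `t_halt_start` and `t_halt_end` both tips are static (halt);
- from `t_halt_end` the **proximal tip** retracts (moves distally) at
  `v_disassembly` µm/min;
- the adhesion is removed outright once its length falls to
  `dissolve_length` (1.0 µm).  Without this abrupt dissolution a
  sub-resolution stub (e.g. 0.3 µm at `v_disassembly` = 0.05 µm/min) would
  linger undetectably for many frames, making "lifespan" unmeasurable in
  principle for any detector; real adhesions disperse once their core
  disassembles.

Rendering uses an anti-aliased rectangle whose edge profile is a 1-px linear
ramp centred on the tip coordinate.  The half-maximum of that profile sits
exactly at the tip, and symmetric PSF blur does not move a symmetric edge's
half-maximum, so half-max tip localization is unbiased by construction —
the analysis is still a genuinely independent measurement (detection,
tracking, axis fitting and sub-pixel tip interpolation all happen on the
rendered images).

The default acquisition is 60 frames at 1 frame/min and 0.16 µm/px (the
pixel size is a convention — typical for a 100×/1.49 NA TIRF EMCCD system —
and is surfaced in every config).  Imaging physics, applied after summing
all objects: Gaussian PSF of `psf_sigma` (default 0.16 µm = 1 px), flat
background (10), Poisson shot noise on `(signal + background) *
poisson_scale` photons, then Gaussian read noise.  `poisson_scale = 1.1`
yields peak SNR ≈ 10 for 100-intensity objects.

`sample_kinetics` draws study populations: assembly speeds uniform on
0.1–1.0 µm/min, disassembly 0.05–0.5 µm/min, integer phase durations
(assembly 4–10 min capped so total extension ≤ 5.5 µm, well inside the
10-µm kymograph line; halt 6–14 min; appearance at 0–4 min).  Anchors are
rejection-sampled ≥ 10 µm apart inside a **peripheral annulus** (edge
distance between ~8.3 and 24 µm): adhesions are peripheral structures, and
on the cell's medial axis the "distal = toward the nearest edge" orientation
is genuinely ill-posed.  A disassembly-knockdown condition is emulated by
scaling every `v_disassembly` (e.g. × 0.5) while keeping all other draws
identical, so paired conditions differ in exactly one mechanism.

### Vesicle fields

Vesicles are Gaussian spots (σ 0.15 µm) whose centres are drawn from the
mixture `(1 − bias) · uniform(cell) + bias · uniform(outer 10 µm band)`;
each performs an optional fixed-step random walk, rejecting steps that leave
the cell.  The truth table records per-frame centres and band membership.

### Colocalization triads

The seven exclusive combinations of three channels receive disjoint pixel
sets realized as compact 5×5-px tiles (2-px gaps) placed on a shuffled grid
inside the cell; a partial tile absorbs any remainder, so requested counts
are met exactly.  Channel masks are unions of the four combinations
containing that channel; each channel image is its mask at uniform intensity
plus background and noise.  Infeasible packings raise with required vs
available pixel counts.

### What the generator does *not* emulate

Photobleaching, stage drift, multi-cell fields, 3-D PSFs, adhesion
splitting/merging, curved growth axes, intensity maturation gradients, and
spatially varying background.  Passing the recovery tests therefore shows
the measurement chain is correct and unbiased under the stated imaging
model, not that it is robust to every artefact of real footage.

## Measurement chain

**Thresholding.**  Default is Otsu computed on the first frame and applied
fixed across the series (one threshold per experiment, mirroring standard
practice).  Otsu assumes a meaningfully bimodal histogram; for sparse bright
objects on a dominant noisy background it splits the background mode
instead, so a robust alternative `robust:K` (median + K·1.4826·MAD, default
K = 8 in the study scenarios) is provided and used whenever foreground is a
small fraction of pixels.  Fixed numeric thresholds are also supported and
recorded in provenance.

**Labelling.**  8-connected components (keeps diagonal adhesion tips
together) with a min-area filter in µm² (default 0.15 µm²); µm→px
conversions round half away from zero and the realized pixel values are
always recorded.

**Tracking.**  Greedy frame-to-frame linking by maximal footprint-overlap
fraction (overlap / smaller footprint), ties broken by centroid distance
then label order; unmatched detections open new tracks; dropouts up to
`max_gap` (default 1 frame) may re-match.  Tracks touching the first or last
frame are flagged censored.

**Growth axis.**  Principal axis of the union of a track's footprints
(second central moments); near-isotropic unions (moment ratio < 1.15) fall
back to the net centroid displacement, and a static isotropic object is an
error.  The distal sign is set by the EDT feature transform — the vector
from the union centroid to its nearest edge pixel — because a
finite-difference probe of the distance map is ambiguous near the medial
axis.  The 10-µm measurement line is centred on the union centroid and
frozen for the track's lifetime (a fixed ruler for ΔD).

**Kymograph and tips.**  The line is sampled at 1-px steps by bilinear
interpolation, averaged over `width_avg` (3) parallel lines 1 px apart.  Per
column, the adhesion extent is the contiguous run at or above background +
50% of (column max − background); run edges are refined by linear
interpolation of the half-max crossing (sub-pixel).  Background is the
median intensity outside the cell mask; columns with contrast below
5 × the robust noise scale are undefined.  With multiple runs (a neighbour
on the line) the run nearest the previous frame's tips is kept; on the first
frame, the brightest.  Tip search is restricted to the track's observed
frame range.

**Event segmentation.**  Frame intervals are classified by tip motion with
a threshold of half of `min_rate·Δt` (hysteresis against sub-threshold
jitter); distal advance takes precedence over proximal advance so classes
stay exclusive and times add up.  Maximal runs spanning ≥ `min_duration`
(3) frames with mean rate ≥ `min_rate` (0.05 µm/min) become assembly or
disassembly events; shorter or slower runs are halt.  Event rates are
least-squares slopes of the *raw* tip series over the segment — identical to
the endpoint ΔD/ΔT for noiseless linear motion and unbiased under tip
jitter (endpoint differences of median-smoothed series were ~15% biased at
SNR 10).  `min_rate`/`min_duration` separate halting from drift; there is
no community-standard numeric criterion, so both are config.

**Per-adhesion metrics.**  Assembly/disassembly rates are means over the
corresponding events and *missing* (NaN) when no event occurred; halt time
sums all halt intervals; lifespan is `(last − first + 1) · frame_interval`
capped at the acquisition duration; event counts are reported raw and per
60 min of observation (the normalization choice is ambiguous, so both are
emitted); censored flags propagate, and censored lifespans are excluded
from summary means by default.  Per track, assembly + disassembly + halt +
undefined-tip time equals the within-track interval time exactly.

**Morphometrics.**  Circularity is `4πA/p²`, reported raw (digitized shapes
may exceed 1).  The perimeter estimator matters: pixel-edge counting biases
circularity ~27% low on disks, and even a raw marching-squares polygon keeps
4–6% staircase excess.  The subpixel mode therefore smooths the mask with a
Gaussian whose width scales with object size (σ = √area_px / 100, floored at
1 px) before contouring at the half level: disks of radius 100 px measure
within 0.1%, a 20-px square within 4.5%, and the measure is stable to ≤ 0.3%
under 2× resampling because the smoothing scales with the shape.  A
pixel-boundary mode is kept for ImageJ parity.  Aspect ratio uses the
moment-equivalent ellipse with the standard +1/12 per-pixel variance term,
which also regularizes collinear masks (a 1-px line has its pixel
footprint's minor axis).

**Colocalization.**  Exclusive combinations are boolean algebra on the
thresholded masks (validated against per-pixel truth-table oracles);
integrated densities of integer images sum in exact int64 arithmetic, making
channel additivity (the four combinations containing X sum to X's in-region
total) bit-exact.  Neighbourhoods are both the 0.8-µm disk dilation of each
reference adhesion and a 5×4 µm crop centred on it (the two region
definitions in circulation are not equivalent, so both are emitted
side-by-side); crops are adhesion-aligned by default (axis-aligned
available) and use half-open [−half, half) membership so a 5×4 µm crop at
0.2 µm/px is exactly 25×20 px.  Overlapping neighbourhoods are processed
independently and flagged.  Fractions are density-weighted by default
(pixel-count mode available); densities are background-subtracted first.

**Peripheral partition.**  The central region is `distance-to-edge ≥
band_width` computed with the Euclidean distance transform (isotropic —
iterated erosion is not), where distance-to-edge is EDT to background pixel
centres minus half a pixel (a pixel adjacent to background lies 0.5 px from
the boundary).  With this convention a 50×30 µm rectangle with a 10 µm band
has a central area of exactly 300 µm², and the band equals a brute-force
integer-squared-distance computation exactly (ties cannot occur because the
effective threshold `(band_px + 0.5)²` is never an integer when `band_px`
is).  A pixel exactly at the band distance is central (≥ rule); per-adhesion
peripheral/central classification is by the centroid pixel's membership in
the central mask, so it inherits the same rule.  A band wider than the
inscribed radius flags an empty central region rather than failing.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 30 adhesions per condition
(60 frames, 0.16 µm/px, 960×688 px, 72×50 µm cell) for noiseless parameter
recovery and the knockdown comparison (3 seeds × 2 conditions); 8–10
adhesions at SNR ≈ 10 for noise robustness; 1000 random 64×64 instances for
mask-algebra oracles; 50 random blobs for partition exactness; 5 seeds × 200
vesicles for enrichment; 16 adhesions for the 2× per-adhesion intensity
scenario.  These sizes give tight recovery statistics while keeping the
whole suite in the minutes range on one CPU.

## Known limitations

- Tracking is greedy and overlap-based: it does not resolve merging or
  dividing adhesions, and fast objects that move more than their own
  footprint per frame will fragment.
- The kymograph line is frozen at track birth; adhesions that genuinely
  rotate their growth axis are measured along a stale ruler.
- Tip localization assumes one dominant intensity plateau per column;
  overlapping adhesions on the same line are disambiguated only by
  proximity to the previous frame.
- The half-max tip criterion matches the simulator's edge model exactly; on
  real footage with asymmetric PSFs or intensity gradients along the
  adhesion it carries a bias that the config (`tip criterion`, `width_avg`,
  `min_contrast`) can only partially compensate.
- Event classification at exactly the `min_rate` boundary is inclusive (≥),
  so speeds equal to the threshold count as events.
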