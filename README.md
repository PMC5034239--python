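# fadyn

Quantification of focal-adhesion (FA) turnover, differential triple
colocalization and peripheral enrichment in fluorescence time-lapse
microscopy — with a matched synthetic-data generator so every measurement
can be validated against known ground truth.

## Who this is for

Cell-migration labs quantify how scaffold proteins (liprin-α1, ERC1, LL5β)
and membrane traffic (Rab6/Rab7 vesicles) regulate the life cycle of focal
adhesions at the protruding edge of migrating cells.  The measurements are
classically done interactively in ImageJ: kymographs traced along each
adhesion's growth axis, binary-mask algebra between thresholded channels,
and peripheral/central splits of the cell footprint.  `fadyn` implements
those procedures as a tested, scriptable pipeline:

- **adhesion turnover** — detect and track FAs in a zyxin/vinculin channel,
  trace a 10 µm kymograph line along each FA's growth axis (distal end
  toward the cell edge), locate the distal and proximal tips per frame at
  half-maximum, and report the assembly rate (distal-tip extension, ΔD/ΔT in
  µm/min), disassembly rate (proximal-tip retraction), halt time, lifespan
  and event counts per adhesion;
- **cell morphometrics** — projected area *A*, perimeter *p*, circularity
  4π·A/p² (1.0 for a perfect circle) and the major/minor-axis aspect ratio;
- **triple colocalization** — the 7 exclusive combinations (A-only … ABC) of
  three thresholded channels inside 0.8 µm neighbourhoods (or 5×4 µm crops)
  around reference adhesions, with integrated-density fractions per channel;
- **peripheral partition** — the central region bounded by the curve
  equidistant 10 µm from the cell edge (Euclidean distance transform, exact
  pixel accounting), peripheral = total − central, and the derived
  Rab-area/cell-area and FA/cell ratios;
- **synthetic data** — seeded simulations of all of the above with truth
  tables: FA ribbons with prescribed extension/retraction speeds, vesicle
  fields with a tunable peripheral placement bias, and 3-channel images
  realizing prescribed exclusive-overlap pixel counts, under Gaussian-PSF
  blur, Poisson shot noise and Gaussian read noise.

## Worked example

Simulate five adhesions with known kinetics and recover them end to end:

```python
import numpy as np
from fadyn import (AcquisitionSpec, sample_kinetics,
                   simulate_adhesion_timelapse, simulate_cell_mask)
from fadyn.dynamics import analyze_turnover

acq = AcquisitionSpec(n_frames=60, frame_interval=1.0, pixel_size=0.16,
                      image_shape=(390, 540), psf_sigma=0.16, background_level=10.0)
cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse",
                          {"semi_axes": (40.0, 28.0)})
kinetics = sample_kinetics(cell, acq.pixel_size, n=5, seed=8)
stack, truth = simulate_adhesion_timelapse(cell, kinetics, acq, seed=8)

result = analyze_turnover(stack, channel="adhesion", cell_mask=cell,
                          threshold="robust:8")
cols = ["track_id", "assembly_rate", "disassembly_rate", "halt_time", "lifespan"]
print(result.per_track[cols].round(3).to_string(index=False))
print("truth assembly rates:   ", np.round(sorted(k.v_assembly for k in kinetics), 3))
print("truth disassembly rates:", np.round(sorted(k.v_disassembly for k in kinetics), 3))
```

prints

```
 track_id  assembly_rate  disassembly_rate  halt_time  lifespan
        0          0.729             0.190       13.0      45.0
        1          0.293             0.421        6.0      21.0
        2          0.458             0.168       10.0      28.0
        3          0.906             0.231       11.0      43.0
        4          0.503             0.334        6.0      18.0

truth assembly rates:    [0.293 0.461 0.502 0.731 0.906]
truth disassembly rates: [0.168 0.19  0.231 0.334 0.42 ]
```

Each track's assembly rate (µm/min, distal-tip extension), disassembly rate
(proximal-tip retraction), summed halt time and lifespan (min) match the
simulated kinetics to ~1%; rates are reported as missing (NaN), never 0,
when no event of that kind was observed.

## Command line

```bash
fadyn simulate --spec spec.yaml --seed 3 --out sim/   # footage + truth CSVs
fadyn run      --config cfg.yaml                      # segment→shape→dynamics→partition
fadyn segment|shape|dynamics|coloc|partition --config cfg.yaml
```

A pipeline run writes per-stage CSVs (`tracks.csv`, `events.csv`,
`shape.csv`, `partition.csv`, …), a `summary.json`, a max-projection PNG and
the resolved `resolved_config.yaml` next to the outputs; reruns with the
same config reproduce the CSVs byte for byte.  All physical parameters are
micrometres and minutes; calibration (µm/px, min/frame) must always be given
explicitly.

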