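"""Configuration, orchestration and reporting for the full pipeline.

A :class:`PipelineConfig` (YAML-round-trippable) drives
``segment -> shape -> dynamics -> coloc -> partition`` on a calibrated
stack; every run writes per-stage CSVs, a JSON summary, and the resolved
configuration next to the outputs so each file is traceable to its
parameters.  Reruns with identical inputs and config reproduce the CSVs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coloc as _coloc
from . import dynamics as _dyn
from . import morphometrics as _morph
from . import partition as _part
from . import prep as _prep
from .stack import ImageStack, read_stack

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    Physical parameters are micrometres and minutes throughout; the config
    round-trips losslessly through YAML.
    """

    input: list[str] | None = None
    layout: str = "tcyx"
    channel_roles: dict = field(default_factory=lambda: {"adhesion": 0})
    pixel_size: float | None = None
    frame_interval: float | None = None
    stages: list[str] = field(default_factory=lambda: ["segment", "shape", "dynamics", "partition"])
    threshold: str = "otsu"
    min_area: float = 0.15  # um^2
    max_gap: int = 1
    line_length: float = 10.0  # um
    width_avg: int = 3
    min_rate: float = 0.05  # um/min
    min_duration: int = 3  # frames
    smooth_window: int = 1
    dilation_distance: float = 0.8  # um
    crop_size: list[float] = field(default_factory=lambda: [5.0, 4.0])  # um
    band_width: float = 10.0  # um
    seed: int = 0
    out_dir: str = "fadyn_out"
    simulate: dict | None = None

    def __post_init__(self) -> None:
        for name in ("line_length", "width_avg", "min_rate", "dilation_distance", "band_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.min_duration < 1 or self.max_gap < 0:
            raise ValueError("min_duration must be >= 1 and max_gap >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _load_or_simulate(config: PipelineConfig):
    """Resolve the input stack: read TIFFs or run a named simulation."""
    if config.simulate:
        from . import studies

        sim = dict(config.simulate)
        kind = sim.pop("kind", "turnover")
        if kind == "turnover":
            stack, truth = studies.turnover_condition(seed=config.seed, **sim)
            return stack, truth
        raise ValueError(f"unknown simulation kind {kind!r}")
    if not config.input:
        raise ValueError("config needs either 'input' paths or a 'simulate' block")
    stack = read_stack(
        config.input,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        layout=config.layout,
        channel_roles=config.channel_roles,
    )
    return stack, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and write the result bundle.

    Returns a dict with in-memory results per stage plus the summary.
    Stage failures abort with the stage name in the error message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth = _load_or_simulate(config)
    adhesion_channel = "adhesion" if "adhesion" in stack.channel_roles else 0

    results: dict = {"stack": stack, "truth": truth}
    summary: dict = {
        "fadyn_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_frames": stack.n_frames,
        "n_channels": stack.n_channels,
        "pixel_size": stack.pixel_size,
        "frame_interval": stack.frame_interval,
        "stages": {},
    }

    cell = None
    if truth is not None:
        cell = truth.cell_mask
    for stage in config.stages:
        try:
            if stage == "segment":
                if cell is None:
                    from scipy import ndimage as ndi

                    proj = ndi.gaussian_filter(stack.max_projection(adhesion_channel), 2.0)
                    cell = _prep.cell_mask(proj)
                masks, thr = _prep.threshold_series(stack.channel(adhesion_channel), config.threshold)
                labels0 = _prep.label_regions(
                    masks[0], min_area=config.min_area, pixel_size=stack.pixel_size,
                    provenance={"threshold": thr, "frame": 0},
                )
                regions = pd.DataFrame(
                    {
                        "label": np.arange(1, labels0.n_labels + 1),
                        "area_um2": labels0.areas_um2(),
                        "centroid_x": labels0.centroids_um()[:, 0] if labels0.n_labels else [],
                        "centroid_y": labels0.centroids_um()[:, 1] if labels0.n_labels else [],
                    }
                )
                _write_csv(regions, out / "adhesions_frame0.csv")
                count, per_um2, frac = _dyn.adhesion_density(labels0, cell)
                results["segment"] = {"cell_mask": cell, "labels0": labels0, "threshold": thr}
                summary["stages"]["segment"] = {
                    "threshold": thr,
                    "n_adhesions_frame0": count,
                    "adhesions_per_um2": per_um2,
                    "adhesion_area_fraction": frac,
                }
            elif stage == "shape":
                if cell is None:
                    raise ValueError("shape stage needs the segment stage first")
                geom = _morph.cell_geometry(cell, stack.pixel_size)
                df = pd.DataFrame([dataclasses.asdict(geom)])
                _write_csv(df, out / "shape.csv")
                results["shape"] = geom
                summary["stages"]["shape"] = dataclasses.asdict(geom)
            elif stage == "dynamics":
                dyn = _dyn.analyze_turnover(
                    stack,
                    channel=adhesion_channel,
                    cell_mask=cell,
                    threshold=config.threshold,
                    min_area=config.min_area,
                    max_gap=config.max_gap,
                    line_length=config.line_length,
                    width_avg=config.width_avg,
                    min_rate=config.min_rate,
                    min_duration=config.min_duration,
                    smooth_window=config.smooth_window,
                )
                _write_csv(dyn.per_track, out / "tracks.csv")
                _write_csv(dyn.events, out / "events.csv")
                _save_projection_png(stack, adhesion_channel, out / "max_projection.png")
                results["dynamics"] = dyn
                pt = dyn.per_track
                summary["stages"]["dynamics"] = {
                    "n_tracks": int(len(pt)),
                    "mean_assembly_rate": _nanmean(pt["assembly_rate"]),
                    "mean_disassembly_rate": _nanmean(pt["disassembly_rate"]),
                    "mean_lifespan": _nanmean(pt["lifespan"]),
                    "mean_halt_time": _nanmean(pt["halt_time"]),
                }
                if cell is None:
                    cell = dyn.cell_mask
            elif stage == "coloc":
                if stack.n_channels < 3:
                    raise ValueError("coloc stage needs a 3-channel stack")
                names = list(stack.channel_roles) or [0, 1, 2]
                images = {str(n): stack.frame(0, n) for n in names[:3]}
                masks = {}
                bgs = {}
                for n, img in images.items():
                    m, _ = _prep.threshold_mask(img, config.threshold)
                    masks[n] = m
                    bgs[n] = float(np.median(img[~m]))
                report = _coloc.coloc_fractions(images, masks, regions=None, background=bgs)
                _write_csv(report.per_region, out / "coloc_regions.csv")
                _write_csv(report.summary, out / "coloc_summary.csv")
                results["coloc"] = report
                summary["stages"]["coloc"] = {
                    "channels": list(images),
                    "n_regions": int(report.per_region["region"].nunique()),
                }
            elif stage == "partition":
                if cell is None:
                    raise ValueError("partition stage needs the segment or dynamics stage first")
                part = _part.partition_cell(cell, band_width=config.band_width, pixel_size=stack.pixel_size)
                masks, _thr = _prep.threshold_series(stack.channel(adhesion_channel), config.threshold)
                sig = _part.peripheral_signal(masks[0] & cell, part)
                df = pd.DataFrame(
                    [
                        {
                            "cell_area_um2": part.cell_area,
                            "central_area_um2": part.central_area,
                            "peripheral_area_um2": part.peripheral_area,
                            "central_empty": part.central_empty,
                            "signal_total_px": sig.total,
                            "signal_central_px": sig.central,
                            "signal_peripheral_px": sig.peripheral,
                            "peripheral_normalized": sig.peripheral_normalized,
                        }
                    ]
                )
                _write_csv(df, out / "partition.csv")
                results["partition"] = part
                summary["stages"]["partition"] = df.iloc[0].to_dict()
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out / "resolved_config.yaml")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    results["summary"] = summary
    return results


def _nanmean(series: pd.Series) -> float:
    arr = series.to_numpy(dtype=float)
    return float(np.nanmean(arr)) if np.isfinite(arr).any() else float("nan")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _save_projection_png(stack: ImageStack, channel, path: Path) -> None:
    """Plumbing: a simple max-intensity-projection visual."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = stack.max_projection(channel)
    plt.imsave(path, proj, cmap="magma")


def export_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Write any DataFrame-valued results as CSVs with fixed float precision.

    Empty frames produce header-only files; returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            path = out / f"{key}.csv"
            _write_csv(value, path)
            written.append(path)
    return written
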