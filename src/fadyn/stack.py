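"""Calibrated multi-channel image stacks.

The canonical in-memory container is a ``T x C x Y x X`` intensity array with
physical calibration: ``pixel_size`` in micrometres per pixel and
``frame_interval`` in minutes per frame.  Physical coordinates are expressed
as ``(x, y)`` in micrometres with ``x = column * pixel_size`` and
``y = row * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A calibrated time-lapse image stack.

    Parameters
    ----------
    data
        Intensities with shape ``(T, C, Y, X)``.
    pixel_size
        Lateral calibration, micrometres per pixel (> 0).
    frame_interval
        Temporal calibration, minutes per frame (> 0).
    channel_roles
        Maps a biological role (``"adhesion"``, ``"scaffold"``, ``"vesicle"``,
        ``"integrin"``, ...) to a channel index.  Roles must be unique.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4-D (T, C, Y, X), got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"all stack dimensions must be >= 1, got {self.data.shape}")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0 um/px, got {self.pixel_size}")
        if not (self.frame_interval > 0):
            raise ValueError(
                f"frame_interval must be > 0 min/frame, got {self.frame_interval}"
            )
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ValueError(f"channel role indices must be unique, got {self.channel_roles}")
        for role, idx in self.channel_roles.items():
            if not (0 <= idx < self.n_channels):
                raise ValueError(
                    f"role {role!r} points at channel {idx}, stack has {self.n_channels}"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in minutes."""
        return np.arange(self.n_frames) * self.frame_interval

    # -- access ---------------------------------------------------------
    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_roles[channel]
            except KeyError:
                raise KeyError(
                    f"unknown channel role {channel!r}; known: {sorted(self.channel_roles)}"
                ) from None
        return int(channel)

    def channel(self, channel: int | str = 0) -> np.ndarray:
        """Return one channel as a ``(T, Y, X)`` view."""
        return self.data[:, self.channel_index(channel)]

    def frame(self, t: int, channel: int | str = 0) -> np.ndarray:
        return self.data[t, self.channel_index(channel)]

    def max_projection(self, channel: int | str = 0) -> np.ndarray:
        """Maximum-intensity projection over time for one channel."""
        return self.channel(channel).max(axis=0)

    # -- i/o --------------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Write the stack as a multipage TIFF with TCYX axes."""
        path = Path(path)
        tifffile.imwrite(path, self.data, metadata={"axes": "TCYX"})
        return path


def read_stack(
    paths: str | Path | Sequence[str | Path],
    *,
    pixel_size: float | None,
    frame_interval: float | None,
    layout: str = "tcyx",
    channel_roles: Mapping[str, int] | None = None,
) -> ImageStack:
    """Read a calibrated stack from one or more multipage TIFF files.

    ``layout`` declares how pages map to dimensions:

    - ``"tcyx"``: a single file holding an interleaved T x C x Y x X series
      (a T x Y x X file is promoted to one channel);
    - ``"tyx"``: one file *per channel*, each holding a T x Y x X series.

    Calibration is never guessed: ``pixel_size`` and ``frame_interval`` must
    be supplied explicitly.
    """
    if pixel_size is None:
        raise ValueError("pixel_size (um/px) is required; refusing to assume a value")
    if frame_interval is None:
        raise ValueError("frame_interval (min/frame) is required; refusing to assume a value")

    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)

    layout = layout.lower()
    if layout == "tcyx":
        if len(paths) != 1:
            raise ValueError(f"layout 'tcyx' expects a single file, got {len(paths)}")
        data = tifffile.imread(paths[0])
        if data.ndim == 3:  # single channel stored as T x Y x X
            data = data[:, None]
        if data.ndim != 4:
            raise ValueError(
                f"{paths[0]}: expected 3-D or 4-D data for layout 'tcyx', got {data.shape}"
            )
    elif layout == "tyx":
        channels = [tifffile.imread(p) for p in paths]
        for p, c in zip(paths, channels):
            if c.ndim == 2:
                c = c[None]
            if c.ndim != 3:
                raise ValueError(f"{p}: expected a T x Y x X series, got shape {c.shape}")
        channels = [c[None] if c.ndim == 2 else c for c in channels]
        shapes = {c.shape for c in channels}
        if len(shapes) != 1:
            raise ValueError(f"per-channel files disagree in shape: {sorted(shapes)}")
        data = np.stack(channels, axis=1)
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'tcyx' or 'tyx'")

    return ImageStack(
        data=data,
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
        channel_roles=dict(channel_roles or {}),
    )
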