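"""Raster/table I/O and the pipeline's core containers.

Conventions used throughout the package: pixel coordinates are 0-based in
(row, col) order with pixel centres at integer coordinates; arc length is
measured in micrometres along a midline from its first point. Pixel size
(µm/px) and frame interval (min) are supplied by the caller or a config
file, never parsed from TIFF tags.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("septaquant")


def configure_logging(verbose: bool = False) -> None:
    """Structured logging to stderr; ``verbose`` switches DEBUG on."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
    logger.setLevel(level)


@dataclass(frozen=True)
class PixelRaster:
    """A single 2-D intensity image in arbitrary units (AU)."""

    values: np.ndarray
    pixel_size: float  # µm/px

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("raster contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class TimeLapseStack:
    """An ordered series of equally shaped frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, rows, cols)
    frame_interval: float  # min
    pixel_size: float  # µm/px
    channel_names: tuple[str, ...] = ("ch0",)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"stack must be 3-D (t, rows, cols), got {frames.shape}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    def __len__(self) -> int:
        return self.frames.shape[0]

    def frame(self, t: int) -> PixelRaster:
        return PixelRaster(self.frames[t], self.pixel_size)

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in minutes, frame 0 at t = 0."""
        return np.arange(len(self)) * self.frame_interval


@dataclass(frozen=True)
class MidlineTrace:
    """An ordered polyline tracing a hypha's centre, in pixel coordinates.

    ``line_halfwidth`` carries the transverse averaging half-width used when
    extracting intensity profiles (a 5-px line corresponds to halfwidth 2).
    """

    hypha_id: str
    points: np.ndarray  # (n, 2) as (x_px, y_px)
    pixel_size: float  # µm/px
    line_halfwidth: int = 2

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("midline needs >= 2 (x, y) points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive midline points must be distinct")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        """Total arc length in µm."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return float(steps.sum() * self.pixel_size)

    def resample(self, spacing_px: float = 1.0) -> np.ndarray:
        """Equally spaced (x, y) samples along the polyline, spacing in px.

        The last sample lands on the final vertex so that the sampled arc
        length matches the polyline's within one sample spacing.
        """
        pts = self.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n = max(int(np.floor(total / spacing_px)) + 1, 2)
        si = np.linspace(0.0, total, n)
        x = np.interp(si, s, pts[:, 0])
        y = np.interp(si, s, pts[:, 1])
        return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(
    path: str | os.PathLike,
    pixel_size: float,
    frame_interval: float,
    channel_names: Sequence[str] = ("ch0",),
) -> TimeLapseStack:
    """Read a multi-page TIFF as a time-lapse stack, page order = frame order."""
    with tifffile.TiffFile(path) as tif:
        pages = [page.asarray() for page in tif.pages]
    if not pages:
        raise ValueError(f"{path}: TIFF contains no pages")
    shape0 = pages[0].shape
    for i, p in enumerate(pages):
        if p.shape != shape0:
            raise ValueError(
                f"{path}: page {i} has shape {p.shape}, expected {shape0}"
            )
    frames = np.stack(pages, axis=0)
    return TimeLapseStack(frames, frame_interval, pixel_size, tuple(channel_names))


def write_stack(stack: TimeLapseStack, path: str | os.PathLike) -> None:
    """Write one TIFF page per frame; float frames stored as float32-compatible."""
    tifffile.imwrite(path, np.asarray(stack.frames), photometric='minisblack')


# ---------------------------------------------------------------------------
# Record tables


def write_table(records: Iterable, path: str | os.PathLike) -> pd.DataFrame:
    """Write a homogeneous list of dataclass records to CSV at full precision.

    Returns the frame that was written. Raises on mixed record types and never
    leaves a partial file behind.
    """
    records = list(records)
    if records:
        first_type = type(records[0])
        if not dataclasses.is_dataclass(records[0]):
            raise TypeError(f"records must be dataclasses, got {first_type}")
        for r in records:
            if type(r) is not first_type:
                raise TypeError(
                    f"mixed record types: {first_type.__name__} and {type(r).__name__}"
                )
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame()
    directory = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"directory does not exist: {directory}")
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    # round_trip parsing so full-precision floats survive the CSV cycle
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Midline CSV (columns: hypha_id, point_index, x_px, y_px)


def write_midlines(midlines: Sequence[MidlineTrace], path: str | os.PathLike) -> None:
    rows = []
    for m in midlines:
        for i, (x, y) in enumerate(m.points):
            rows.append(
                {"hypha_id": m.hypha_id, "point_index": i, "x_px": x, "y_px": y}
            )
    pd.DataFrame(rows, columns=["hypha_id", "point_index", "x_px", "y_px"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_midlines(
    path: str | os.PathLike, pixel_size: float, line_halfwidth: int = 2
) -> list[MidlineTrace]:
    df = pd.read_csv(path)
    out = []
    for hid, grp in df.groupby("hypha_id", sort=False):
        grp = grp.sort_values("point_index")
        pts = grp[["x_px", "y_px"]].to_numpy(float)
        out.append(MidlineTrace(str(hid), pts, pixel_size, line_halfwidth))
    return out
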