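"""Kymographs, line profiles and dual-channel co-localization.

A kymograph stacks the intensity profile along a (frozen) hypha midline for
every frame: rows are frames, columns are arc-length samples. The midline is
taken from the final, non-growing configuration of the hypha, which is where
septal rings assemble.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import tifffile

from .imgio import MidlineTrace, PixelRaster, TimeLapseStack
from .preprocess import straighten


@dataclass(frozen=True)
class LineProfile:
    """Intensity versus arc-length position along a midline."""

    positions: np.ndarray  # µm, ascending
    intensities: np.ndarray  # AU
    channel: str = "ch0"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1-D")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class Kymograph:
    grid: np.ndarray  # rows = frames, cols = arc samples
    frame_interval: float  # min
    sample_spacing: float  # µm between arc samples
    midline_ref: str = "h0"

    def row_profile(self, t: int) -> LineProfile:
        cols = self.grid.shape[1]
        return LineProfile(np.arange(cols) * self.sample_spacing, self.grid[t])


def profile_along_line(
    raster: PixelRaster,
    midline: MidlineTrace,
    linewidth_px: int = 5,
    channel: str = "ch0",
) -> LineProfile:
    """Mean intensity over a transverse band of ``linewidth_px`` at each
    arc-length sample (1-px spacing), positions in µm."""
    half = max((linewidth_px - 1) // 2, 0)
    band = straighten(raster, midline, half_width_px=half)
    intensities = band.values.mean(axis=0)
    # straightening samples the polyline uniformly from end to end, so the
    # true sample spacing is arc_length/(n-1), marginally under 1 px
    positions = np.linspace(0.0, midline.arc_length, intensities.size)
    return LineProfile(positions, intensities, channel)


def build_kymograph(
    stack: TimeLapseStack, midline: MidlineTrace, linewidth_px: int = 5
) -> Kymograph:
    """Row t of the kymograph is the line profile of frame t."""
    rows = []
    for t in range(len(stack)):
        try:
            rows.append(profile_along_line(stack.frame(t), midline, linewidth_px))
        except ValueError as err:
            raise ValueError(f"frame {t}: {err}") from err
    grid = np.stack([r.intensities for r in rows], axis=0)
    spacing = float(rows[0].positions[1] - rows[0].positions[0])
    return Kymograph(grid, stack.frame_interval, spacing, midline.hypha_id)


def average_projection(stack: TimeLapseStack) -> PixelRaster:
    """Pixel-wise mean across all frames."""
    if len(stack) < 1:
        raise ValueError("empty stack")
    return PixelRaster(
        np.asarray(stack.frames, dtype=float).mean(axis=0), stack.pixel_size
    )


def dual_channel_profiles(
    raster_a: PixelRaster,
    raster_b: PixelRaster,
    midline: MidlineTrace,
    linewidth_px: int = 5,
    channels: tuple[str, str] = ("chA", "chB"),
) -> tuple[LineProfile, LineProfile, float]:
    """Profiles of two channels on one position grid plus their Pearson
    correlation as a co-localization score in [-1, 1]."""
    if raster_a.shape != raster_b.shape:
        raise ValueError(
            f"channel shapes differ: {raster_a.shape} vs {raster_b.shape}"
        )
    if raster_a.pixel_size != raster_b.pixel_size:
        raise ValueError("channel pixel sizes differ")
    prof_a = profile_along_line(raster_a, midline, linewidth_px, channels[0])
    prof_b = profile_along_line(raster_b, midline, linewidth_px, channels[1])
    a = prof_a.intensities
    b = prof_b.intensities
    if a.std() == 0 or b.std() == 0:
        score = 0.0
    else:
        score = float(np.corrcoef(a, b)[0, 1])
    return prof_a, prof_b, score


def write_kymograph(kymo: Kymograph, path: str | os.PathLike) -> None:
    """TIFF image plus a JSON sidecar carrying the axis metadata."""
    tifffile.imwrite(path, np.asarray(kymo.grid, dtype=np.float32))
    sidecar = os.fspath(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "frame_interval_min": kymo.frame_interval,
                "sample_spacing_um": kymo.sample_spacing,
                "midline_ref": kymo.midline_ref,
            },
            fh,
            indent=2,
        )


def read_kymograph(path: str | os.PathLike) -> Kymograph:
    grid = tifffile.imread(path)
    with open(os.fspath(path) + ".json") as fh:
        meta = json.load(fh)
    return Kymograph(
        np.asarray(grid, dtype=float),
        meta["frame_interval_min"],
        meta["sample_spacing_um"],
        meta.get("midline_ref", "h0"),
    )
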