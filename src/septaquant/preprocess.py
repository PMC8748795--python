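"""Registration, background correction and hypha straightening.

These are the steps applied to a raw time-lapse stack before any
quantification: frames are aligned by rigid translation, background
fluorescence is removed per frame using multi-class Otsu thresholding (the
lowest class is taken as background), and curved hyphae are resampled into a
straight axis-aligned band for profile and kymograph extraction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.registration import phase_cross_correlation

from .imgio import MidlineTrace, PixelRaster, TimeLapseStack, logger


def register_stack(
    stack: TimeLapseStack, upsample_factor: int = 20
) -> tuple[TimeLapseStack, np.ndarray]:
    """Align every frame to the first by planar translation.

    Shifts are estimated by phase cross-correlation at sub-pixel resolution
    and applied with bilinear interpolation; pixels shifted in from outside
    the canvas are filled with the frame's median (a robust background
    estimate). Returns the registered stack and the (n_frames, 2) array of
    applied (row, col) shifts.
    """
    if len(stack) < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = np.asarray(stack.frames[0], dtype=float)
    registered = np.empty_like(stack.frames, dtype=float)
    registered[0] = ref
    shifts = np.zeros((len(stack), 2))
    for t in range(1, len(stack)):
        frame = np.asarray(stack.frames[t], dtype=float)
        if frame.std() == 0 or ref.std() == 0:
            logger.warning("frame %d has zero variance; assuming zero shift", t)
            registered[t] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor
        )
        shifts[t] = shift
        registered[t] = ndimage.shift(
            frame, shift, order=1, mode="constant", cval=float(np.median(frame))
        )
    out = TimeLapseStack(
        registered, stack.frame_interval, stack.pixel_size, stack.channel_names
    )
    return out, shifts


def background_correct_multiotsu(
    raster: PixelRaster, n_classes: int = 3, stat: str = "mean", clip: bool = True
) -> PixelRaster:
    """Subtract the multi-Otsu background class from every pixel, clipped at 0.

    Thresholds are computed on the intensity histogram for ``n_classes``
    classes (background / cytoplasm / septa by default); pixels at or below
    the lowest threshold form the background class whose mean (or median,
    ``stat="median"``) is subtracted. Degenerate rasters with fewer distinct
    values than classes fall back to fewer classes; a constant raster maps
    to zeros. ``clip=False`` keeps negative residuals, which leaves ROI
    averages of noisy background unbiased (clipping adds a positive bias in
    dim regions).
    """
    values = np.asarray(raster.values, dtype=float)
    n_unique = np.unique(values).size
    if n_unique == 1:
        logger.debug("constant raster: background correction returns zeros")
        return PixelRaster(np.zeros_like(values), raster.pixel_size)
    classes = min(n_classes, n_unique)
    thresholds = threshold_multiotsu(values, classes=classes)
    background_mask = values <= thresholds[0]
    reducer = np.median if stat == "median" else np.mean
    background = float(reducer(values[background_mask]))
    corrected = values - background
    if clip:
        corrected = np.clip(corrected, 0.0, None)
    return PixelRaster(corrected, raster.pixel_size)


def background_correct_stack(
    stack: TimeLapseStack,
    n_classes: int = 3,
    stat: str = "median",
    clip: bool = False,
) -> TimeLapseStack:
    """Per-frame multi-Otsu background subtraction with a temporally stable
    background region.

    The background class is segmented once on the pixel-wise average
    projection (where rings, cytoplasm and background are all represented,
    so the class structure is well defined), and each frame subtracts its
    own background level — the ``stat`` (median by default, robust to
    class-edge pixels) over that fixed region. The top decile of the class
    (by projection value) is trimmed off: those pixels sit against the
    threshold, where segmentation noise lets dim foreground leak in and
    bias the level upward. This keeps the correction per-frame while
    avoiding frame-to-frame threshold wobble on frames whose intensity
    histogram is degenerate (e.g. after ring disassembly).
    """
    projection = np.asarray(stack.frames, dtype=float).mean(axis=0)
    n_unique = np.unique(projection).size
    if n_unique == 1:
        mask = np.ones_like(projection, dtype=bool)
    else:
        thresholds = threshold_multiotsu(
            projection, classes=min(n_classes, n_unique)
        )
        mask = projection <= thresholds[0]
        mask &= projection <= np.quantile(projection[mask], 0.9)
    reducer = np.median if stat == "median" else np.mean
    frames = np.asarray(stack.frames, dtype=float).copy()
    for t in range(frames.shape[0]):
        frames[t] -= float(reducer(frames[t][mask]))
    if clip:
        frames = np.clip(frames, 0.0, None)
    return TimeLapseStack(
        frames, stack.frame_interval, stack.pixel_size, stack.channel_names
    )


def background_subtract_measured(
    raster: PixelRaster, region: tuple[int, int, int, int]
) -> PixelRaster:
    """Subtract the mean of a user-chosen background rectangle, clipped at 0.

    ``region`` is (row_start, row_stop, col_start, col_stop), half-open as in
    array slicing.
    """
    r0, r1, c0, c1 = region
    rows, cols = raster.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"region {region} outside raster of shape {raster.shape}")
    background = float(np.mean(raster.values[r0:r1, c0:c1]))
    corrected = np.clip(np.asarray(raster.values, dtype=float) - background, 0.0, None)
    return PixelRaster(corrected, raster.pixel_size)


def straighten(
    raster: PixelRaster, midline: MidlineTrace, half_width_px: int | None = None
) -> PixelRaster:
    """Resample the band around a midline into a straight raster.

    Output rows are transverse offsets in [-half_width, +half_width] px
    (midline at the centre row), columns are arc-length samples at 1-px
    spacing; values come from bilinear interpolation. The output column
    count times the pixel size matches the midline arc length within 1%.
    """
    if half_width_px is None:
        half_width_px = midline.line_halfwidth
    rows, cols = raster.shape
    pts = midline.points
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= cols - 1)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= rows - 1)
    )
    if not np.all(inside):
        bad = int(np.argmin(inside))
        raise ValueError(
            f"midline {midline.hypha_id!r} exits the raster at point {bad}: "
            f"{tuple(pts[bad])}"
        )
    samples = midline.resample(spacing_px=1.0)
    x, y = samples[:, 0], samples[:, 1]
    tx = np.gradient(x)
    ty = np.gradient(y)
    norm = np.hypot(tx, ty)
    tx, ty = tx / norm, ty / norm
    nx, ny = -ty, tx  # unit normal
    offsets = np.arange(-half_width_px, half_width_px + 1, dtype=float)
    sample_x = x[None, :] + offsets[:, None] * nx[None, :]
    sample_y = y[None, :] + offsets[:, None] * ny[None, :]
    values = ndimage.map_coordinates(
        np.asarray(raster.values, dtype=float),
        [sample_y, sample_x],
        order=1,
        mode="nearest",
    )
    return PixelRaster(values, raster.pixel_size)
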