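"""Z-ring detection and quantification on intensity profiles.

The analysis chain mirrors how septal-ring figures are produced from
time-lapse data of filamentous bacteria: peaks on a background-corrected
axial intensity profile are candidate rings; peaks dimmer than a fixed
intensity filter (default 100 AU) are discarded as false positives; each
surviving ring's axial width is the full width at half maximum (FWHM) of its
peak above the local flanking-valley baseline, and ring spacing is the
distance between neighbouring apexes. Per-ring fluorescence kinetics are
read from a small ROI (10 px along the hypha axis x 20 px across, by
default) on the straightened frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal, stats

from .imgio import MidlineTrace, TimeLapseStack, logger
from .kymo import LineProfile
from .preprocess import straighten


@dataclass(frozen=True)
class RingPeak:
    """One detected septal band on an intensity profile."""

    hypha_id: str
    position: float  # µm, apex arc position
    apex_intensity: float  # AU
    baseline: float  # AU, flanking-valley minimum
    width_fwhm: float  # µm; NaN when censored
    left_half_pos: float  # µm; NaN when censored
    right_half_pos: float  # µm; NaN when censored
    censored: bool = False  # half level not crossed on a flank


@dataclass(frozen=True)
class RingTrace:
    """Per-frame mean ROI intensity of one ring."""

    hypha_id: str
    ring_index: int
    times: np.ndarray  # min
    mean_roi_intensity: np.ndarray  # AU
    roi_shape: tuple[int, int] = (10, 20)  # (along axis, across axis) px

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.mean_roi_intensity, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and intensities must match in length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mean_roi_intensity", v)


@dataclass(frozen=True)
class ReplicateRingStats:
    replicate_id: str
    mean_width: float  # µm
    ci_width: float  # 95% CI half-width, µm
    mean_spacing: float  # µm
    ci_spacing: float  # 95% CI half-width, µm
    n_rings: int
    n_hyphae: int
    n_censored: int


@dataclass(frozen=True)
class RingStatsSummary:
    replicates: tuple[ReplicateRingStats, ...]

    @property
    def mean_width(self) -> float:
        """Grand mean of the per-replicate mean widths."""
        return float(np.mean([r.mean_width for r in self.replicates]))

    @property
    def mean_spacing(self) -> float:
        vals = [r.mean_spacing for r in self.replicates if not math.isnan(r.mean_spacing)]
        return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# peak detection


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat-topped peak reports the middle
    sample of its plateau. Profile ends are never maxima."""
    peaks, _ = signal.find_peaks(x, plateau_size=1)
    return peaks


def _merge_close(
    indices: np.ndarray, apexes: np.ndarray, min_separation_px: int
) -> list[int]:
    """Greedy left-to-right merge: neighbours closer than the separation keep
    the higher apex; equal apexes keep the leftmost."""
    kept: list[tuple[int, float]] = []
    for idx, apex in zip(indices, apexes):
        if kept and idx - kept[-1][0] < min_separation_px:
            if apex > kept[-1][1]:
                kept[-1] = (int(idx), float(apex))
        else:
            kept.append((int(idx), float(apex)))
    return [k for k, _ in kept]


def fwhm(
    profile: LineProfile, apex_index: int, zero_baseline: bool = False
) -> tuple[float, float, float, float, bool]:
    """Full width at half maximum of the peak at ``apex_index``.

    Baseline is the minimum of the two flanking-valley intensities (nearest
    local minimum on each side, or the profile ends); with
    ``zero_baseline=True`` the half level is measured from zero instead.
    Half-level crossings are located by linear interpolation between samples
    on each flank. Returns (width µm, left crossing µm, right crossing µm,
    baseline AU, censored): a peak whose half level is never crossed on one
    flank (e.g. at a profile edge) is censored and its width is NaN.
    """
    y = profile.intensities
    x = profile.positions
    n = y.size
    if n < 3 or not 0 <= apex_index < n:
        raise ValueError(f"apex_index {apex_index} out of range for length {n}")
    apex = float(y[apex_index])

    # nearest local minimum on each side (plateaus walked through)
    i = apex_index
    while i - 1 >= 0 and y[i - 1] <= y[i]:
        i -= 1
    left_valley = i
    j = apex_index
    while j + 1 <= n - 1 and y[j + 1] <= y[j]:
        j += 1
    right_valley = j

    baseline = 0.0 if zero_baseline else float(min(y[left_valley], y[right_valley]))
    if apex <= baseline:
        raise ValueError("apex does not rise above baseline")
    half = baseline + (apex - baseline) / 2.0

    def _cross(from_idx: int, to_idx: int, step: int) -> float:
        k = from_idx
        while k != to_idx:
            k_next = k + step
            if y[k_next] <= half:
                frac = (y[k] - half) / (y[k] - y[k_next])
                return float(x[k] + frac * (x[k_next] - x[k]))
            k = k_next
        return float("nan")

    left_pos = _cross(apex_index, left_valley, -1)
    right_pos = _cross(apex_index, right_valley, +1)
    if math.isnan(left_pos) or math.isnan(right_pos):
        return float("nan"), float("nan"), float("nan"), baseline, True
    return right_pos - left_pos, left_pos, right_pos, baseline, False


def detect_rings(
    profile: LineProfile,
    min_intensity: float = 100.0,
    min_separation_px: int = 3,
    hypha_id: str = "h0",
    use_prominence: bool = False,
    zero_baseline: bool = False,
) -> list[RingPeak]:
    """Detect septal rings as filtered local maxima of an intensity profile.

    Local maxima (strict neighbour comparison, flat tops reporting their
    middle sample) are filtered by apex intensity below ``min_intensity``
    (with ``use_prominence=True`` the filter applies to apex minus the
    flanking-valley baseline instead); survivors closer than
    ``min_separation_px`` samples are merged keeping the higher apex
    (leftmost on ties), and each remaining peak is completed into a
    :class:`RingPeak` via :func:`fwhm`.
    """
    y = profile.intensities
    if y.size < 3:
        return []
    maxima = _local_maxima(y)
    if maxima.size == 0:
        return []

    if use_prominence:
        heights = []
        for m in maxima:
            i = m
            while i - 1 >= 0 and y[i - 1] <= y[i]:
                i -= 1
            j = m
            while j + 1 <= y.size - 1 and y[j + 1] <= y[j]:
                j += 1
            heights.append(y[m] - min(y[i], y[j]))
        heights = np.asarray(heights)
    else:
        heights = y[maxima]
    keep = heights >= min_intensity
    maxima = maxima[keep]
    if maxima.size == 0:
        return []

    kept = _merge_close(maxima, y[maxima], min_separation_px)

    peaks: list[RingPeak] = []
    for idx in kept:
        width, left, right, baseline, censored = fwhm(
            profile, idx, zero_baseline=zero_baseline
        )
        peaks.append(
            RingPeak(
                hypha_id=hypha_id,
                position=float(profile.positions[idx]),
                apex_intensity=float(y[idx]),
                baseline=baseline,
                width_fwhm=width,
                left_half_pos=left,
                right_half_pos=right,
                censored=censored,
            )
        )
    return peaks


def ring_spacings(peaks: Sequence[RingPeak]) -> np.ndarray:
    """Distances (µm) between neighbouring apexes; empty below 2 peaks."""
    positions = np.sort([p.position for p in peaks])
    if positions.size < 2:
        return np.empty(0)
    return np.diff(positions)


# ---------------------------------------------------------------------------
# per-ring kinetics


def ring_time_trace(
    stack: TimeLapseStack,
    midline: MidlineTrace,
    ring_position: float,
    roi_shape: tuple[int, int] = (10, 20),
    ring_index: int = 0,
) -> RingTrace:
    """Mean intensity inside an ROI centred on a ring, per frame.

    The ROI lives in straightened coordinates: ``roi_shape[0]`` samples along
    the hypha axis and ``roi_shape[1]`` across it, centred on the ring's arc
    position. ROIs that would overhang the straightened band are clipped
    with a warning.
    """
    along, across = roi_shape
    if not (0.0 <= ring_position <= midline.arc_length):
        raise ValueError(
            f"ring position {ring_position:.2f} µm outside midline span "
            f"[0, {midline.arc_length:.2f}] µm"
        )
    half_across = across // 2
    centre_col = int(round(ring_position / stack.pixel_size))
    col_lo = centre_col - along // 2
    col_hi = col_lo + along
    values = []
    for t in range(len(stack)):
        band = straighten(stack.frame(t), midline, half_width_px=half_across)
        n_rows, n_cols = band.shape
        lo = max(col_lo, 0)
        hi = min(col_hi, n_cols)
        if (lo, hi) != (col_lo, col_hi) and t == 0:
            logger.warning(
                "ROI clipped to columns [%d, %d) for ring at %.2f µm",
                lo, hi, ring_position,
            )
        row_lo = max(n_rows // 2 - across // 2, 0)
        roi = band.values[row_lo : row_lo + across, lo:hi]
        values.append(float(roi.mean()))
    return RingTrace(
        hypha_id=midline.hypha_id,
        ring_index=ring_index,
        times=stack.times,
        mean_roi_intensity=np.asarray(values),
        roi_shape=roi_shape,
    )


def detect_onset(trace: RingTrace, fraction: float = 0.2) -> int:
    """First frame at which the trace rises above baseline by ``fraction``
    of its dynamic range; 0 for a flat trace."""
    v = trace.mean_roi_intensity
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return 0
    threshold = lo + fraction * (hi - lo)
    above = np.nonzero(v >= threshold)[0]
    return int(above[0]) if above.size else 0


def mean_trace(
    traces: Sequence[RingTrace], align: str = "first"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and s.e.m. over ring traces.

    ``align="first"`` averages frame-by-frame; ``align="onset"`` shifts each
    trace so its detected fluorescence onset sits at time 0 before
    averaging. Returns (times min, mean, s.e.m., n per time point); time
    points covered by a single trace get s.e.m. 0.
    """
    if not traces:
        raise ValueError("need at least one trace")
    intervals = {
        float(np.round(np.diff(t.times).min(), 9)) for t in traces if t.times.size >= 2
    }
    if len(intervals) > 1:
        raise ValueError(f"mixed frame intervals: {sorted(intervals)}")
    interval = intervals.pop() if intervals else 1.0

    offsets = [detect_onset(t) if align == "onset" else 0 for t in traces]
    rel_lo = min(-o for o in offsets)
    rel_hi = max(t.times.size - 1 - o for t, o in zip(traces, offsets))
    grid = np.arange(rel_lo, rel_hi + 1)
    sums = np.zeros(grid.size)
    sq_sums = np.zeros(grid.size)
    counts = np.zeros(grid.size, dtype=int)
    for t, o in zip(traces, offsets):
        rel = np.arange(t.times.size) - o
        idx = rel - rel_lo
        sums[idx] += t.mean_roi_intensity
        sq_sums[idx] += t.mean_roi_intensity**2
        counts[idx] += 1
    mean = np.full(grid.size, np.nan)
    sem = np.zeros(grid.size)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    multi = counts > 1
    var = np.zeros(grid.size)
    var[multi] = (
        sq_sums[multi] - counts[multi] * mean[multi] ** 2
    ) / (counts[multi] - 1)
    sem[multi] = np.sqrt(np.clip(var[multi], 0.0, None) / counts[multi])
    return grid * interval, mean, sem, counts


# ---------------------------------------------------------------------------
# replicate aggregation


def aggregate_ring_stats(
    per_hypha_peaks: Mapping[str, Sequence[RingPeak]],
    n_replicates: int = 1,
    replicate_of: Mapping[str, str] | None = None,
) -> RingStatsSummary:
    """Per-replicate mean ring width and spacing with 95% t-based CIs.

    Widths (censored rings excluded but counted) and within-hypha spacings
    are pooled over each replicate's hyphae; hyphae are assigned to
    replicates by ``replicate_of`` or round-robin over sorted hypha ids.
    """
    hypha_ids = sorted(per_hypha_peaks)
    if replicate_of is None:
        replicate_of = {
            hid: f"rep{i % n_replicates}" for i, hid in enumerate(hypha_ids)
        }
    groups: dict[str, list[str]] = {}
    for hid in hypha_ids:
        groups.setdefault(replicate_of[hid], []).append(hid)

    replicates = []
    total_rings = 0
    for rep_id in sorted(groups):
        widths: list[float] = []
        spacings: list[float] = []
        n_rings = 0
        n_censored = 0
        for hid in groups[rep_id]:
            peaks = list(per_hypha_peaks[hid])
            n_rings += len(peaks)
            n_censored += sum(p.censored for p in peaks)
            widths.extend(p.width_fwhm for p in peaks if not p.censored)
            spacings.extend(ring_spacings(peaks))
        total_rings += n_rings

        def _ci(values: list[float]) -> tuple[float, float]:
            if not values:
                return float("nan"), float("nan")
            arr = np.asarray(values)
            m = float(arr.mean())
            if arr.size < 2:
                return m, float("nan")
            se = float(arr.std(ddof=1) / math.sqrt(arr.size))
            return m, float(stats.t.ppf(0.975, arr.size - 1) * se)

        mean_w, ci_w = _ci(widths)
        mean_s, ci_s = _ci(spacings)
        replicates.append(
            ReplicateRingStats(
                replicate_id=rep_id,
                mean_width=mean_w,
                ci_width=ci_w,
                mean_spacing=mean_s,
                ci_spacing=ci_s,
                n_rings=n_rings,
                n_hyphae=len(groups[rep_id]),
                n_censored=n_censored,
            )
        )
    if total_rings == 0:
        raise ValueError("no usable rings to aggregate")
    return RingStatsSummary(tuple(replicates))
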