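"""End-to-end convenience chains tying the modules together.

These are the exact sequences the analysis drivers and the acceptance
checks run: project the time series, correct the background, profile along
the midline, detect rings, and measure widths/spacings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import MidlineTrace, TimeLapseStack
from .kymo import LineProfile, average_projection, profile_along_line
from .preprocess import background_correct_multiotsu, background_correct_stack
from .rings import RingPeak, RingTrace, detect_rings, ring_spacings, ring_time_trace


@dataclass(frozen=True)
class MovieRingAnalysis:
    profile: LineProfile
    peaks: tuple[RingPeak, ...]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])

    @property
    def widths(self) -> np.ndarray:
        return np.array([p.width_fwhm for p in self.peaks if not p.censored])

    @property
    def spacings(self) -> np.ndarray:
        return ring_spacings(list(self.peaks))


def analyze_movie_rings(
    stack: TimeLapseStack,
    midline: MidlineTrace,
    min_intensity: float = 100.0,
    min_separation_px: int = 3,
    linewidth_px: int = 5,
) -> MovieRingAnalysis:
    """Ring positions, widths and spacings from one sporulation movie.

    Average-intensity projection -> multi-Otsu background correction ->
    5-px line profile along the midline -> peak detection with the
    100 AU false-positive filter -> FWHM widths and neighbour spacings.
    """
    projection = average_projection(stack)
    corrected = background_correct_multiotsu(projection)
    profile = profile_along_line(corrected, midline, linewidth_px)
    peaks = detect_rings(
        profile, min_intensity, min_separation_px, hypha_id=midline.hypha_id
    )
    return MovieRingAnalysis(profile=profile, peaks=tuple(peaks))


def extract_ring_traces(
    stack: TimeLapseStack,
    midline: MidlineTrace,
    ring_positions: np.ndarray,
    roi_shape: tuple[int, int] = (10, 20),
    correct_background: bool = True,
) -> list[RingTrace]:
    """Per-ring ROI kinetic traces from a movie.

    Frames are background-corrected per frame (multi-Otsu background region
    segmented on the average projection, per-frame median level, no
    clipping) so that ROI means over dim regions stay unbiased under noise.
    """
    if correct_background:
        stack = background_correct_stack(stack)
    return [
        ring_time_trace(stack, midline, float(pos), roi_shape, ring_index=i)
        for i, pos in enumerate(ring_positions)
    ]
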