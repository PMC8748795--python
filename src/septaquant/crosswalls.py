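"""Cross-wall frequency analysis in vegetative hyphae.

Septa labelled with a fluorescent cell-wall probe appear as bright
transverse bands; counting them per hypha and regressing the count on
hyphal length gives the septation frequency, whose reciprocal slope is the
mean distance between cross-walls (wild-type filamentous actinomycetes lay
one down every 20-30 µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .imgio import MidlineTrace, PixelRaster
from .kymo import profile_along_line
from .rings import detect_rings


@dataclass(frozen=True)
class CrosswallRecord:
    hypha_id: str
    replicate_id: str
    hyphal_length: float  # µm
    crosswall_count: int
    positions: tuple[float, ...] = ()  # µm, ascending

    def __post_init__(self) -> None:
        if self.hyphal_length <= 0:
            raise ValueError("hyphal_length must be positive")
        if self.crosswall_count != len(self.positions):
            raise ValueError("crosswall_count must equal len(positions)")
        for p in self.positions:
            if not 0.0 <= p <= self.hyphal_length:
                raise ValueError(f"position {p} outside [0, {self.hyphal_length}]")
        object.__setattr__(self, "positions", tuple(sorted(self.positions)))


@dataclass(frozen=True)
class RegressionFit:
    slope: float  # cross-walls per µm
    intercept: float  # cross-walls
    r_squared: float
    n_hyphae: int
    replicate_id: str = "pooled"


def count_crosswalls(
    raster: PixelRaster,
    midline: MidlineTrace,
    min_intensity: float = 100.0,
    min_separation_px: int = 3,
    replicate_id: str = "r1",
    linewidth_px: int = 5,
) -> CrosswallRecord:
    """Count septa along one hypha using the ring peak detector.

    The intensity profile is extracted along the midline and septa are the
    detected peaks; cross-wall bands and cytoplasmic background live on a
    different channel than division rings, so the intensity filter is
    independently configurable.
    """
    profile = profile_along_line(raster, midline, linewidth_px)
    peaks = detect_rings(
        profile, min_intensity, min_separation_px, hypha_id=midline.hypha_id
    )
    length = midline.arc_length
    positions = tuple(p.position for p in peaks if 0.0 <= p.position <= length)
    return CrosswallRecord(
        hypha_id=midline.hypha_id,
        replicate_id=replicate_id,
        hyphal_length=length,
        crosswall_count=len(positions),
        positions=positions,
    )


def crosswall_regression(
    records: Sequence[CrosswallRecord],
    per_replicate: bool = True,
    through_origin: bool = False,
) -> list[RegressionFit]:
    """Ordinary least squares of cross-wall count on hyphal length.

    One fit per replicate when ``per_replicate`` (plus nothing else), else a
    single pooled fit; ``through_origin`` drops the intercept.
    """
    if per_replicate:
        groups = {}
        for r in records:
            groups.setdefault(r.replicate_id, []).append(r)
    else:
        groups = {"pooled": list(records)}

    fits = []
    for rep_id in sorted(groups):
        recs = groups[rep_id]
        if len(recs) < 2:
            raise ValueError(f"replicate {rep_id!r}: need >= 2 hyphae for a fit")
        x = np.array([r.hyphal_length for r in recs])
        y = np.array([float(r.crosswall_count) for r in recs])
        if np.all(y == 0):
            fits.append(RegressionFit(0.0, 0.0, 0.0, len(recs), rep_id))
            continue
        if np.ptp(x) == 0:
            raise ValueError(
                f"replicate {rep_id!r}: all hyphal lengths equal; slope undefined"
            )
        design = x[:, None] if through_origin else sm.add_constant(x)
        model = sm.OLS(y, design).fit()
        if through_origin:
            slope, intercept = float(model.params[0]), 0.0
        else:
            intercept, slope = (float(p) for p in model.params)
        fits.append(
            RegressionFit(
                slope=slope,
                intercept=intercept,
                r_squared=float(model.rsquared),
                n_hyphae=len(recs),
                replicate_id=rep_id,
            )
        )
    return fits


def mean_spacing(fit: RegressionFit) -> float:
    """Mean distance per cross-wall, µm: the reciprocal regression slope."""
    if fit.slope <= 0:
        raise ValueError(
            f"slope {fit.slope} is not positive; mean spacing undefined"
        )
    return 1.0 / fit.slope
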