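"""Synthetic fluorescent-hypha movies, cross-wall snapshots and particle samples.

The generator emulates the three kinds of data the quantification pipeline
consumes, each with an exact ground-truth record:

* sporulating hyphae imaged in time lapse: the hypha grows at the tip until a
  cessation frame, after which a ladder of septal rings appears in the tip
  compartment, each ring's fluorescence rising to a peak and then decaying as
  the ring matures, constricts and disassembles;
* vegetative hyphae labelled for nascent septal wall material, with
  cross-walls placed by a Poisson (i.i.d. exponential gap) process along the
  filament;
* replicate particle-volume samples from a unimodal (log-normal) spore
  population, as a Coulter counter would record them.

Randomness is split into two independent streams per simulation — one for
object placement, one for pixel noise — so that rendering the same ground
truth with and without objects consumes identical noise draws. All outputs
are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import SimulationConfig
from .imgio import MidlineTrace, PixelRaster, TimeLapseStack

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class RingTruth:
    """Simulator record of one septal ring."""

    arc_position: float  # µm along the midline
    onset_frame: int
    peak_frame: int
    amplitude: float  # AU apex above cytoplasm at maturity
    axial_sigma: float  # µm


@dataclass(frozen=True)
class CrosswallTruth:
    hypha_id: str
    arc_position: float  # µm


@dataclass
class GroundTruth:
    """Everything the simulator placed, used as the test oracle downstream."""

    rings: list[RingTruth] = field(default_factory=list)
    crosswalls: list[CrosswallTruth] = field(default_factory=list)
    hypha_lengths: dict[str, float] = field(default_factory=dict)
    particle_params: list[tuple[float, float, int]] = field(default_factory=list)
    midlines: dict[str, list[list[float]]] = field(default_factory=dict)
    seed: int = 0

    def crosswalls_of(self, hypha_id: str) -> list[float]:
        return sorted(
            cw.arc_position for cw in self.crosswalls if cw.hypha_id == hypha_id
        )

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = {
            "rings": [vars(r) for r in self.rings],
            "crosswalls": [vars(c) for c in self.crosswalls],
            "hypha_lengths": self.hypha_lengths,
            "particle_params": [list(p) for p in self.particle_params],
            "midlines": self.midlines,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "GroundTruth":
        if os.path.exists(text_or_path):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(text_or_path)
        return cls(
            rings=[RingTruth(**r) for r in payload["rings"]],
            crosswalls=[CrosswallTruth(**c) for c in payload["crosswalls"]],
            hypha_lengths=dict(payload["hypha_lengths"]),
            particle_params=[tuple(p) for p in payload["particle_params"]],
            midlines={k: [list(p) for p in v] for k, v in payload["midlines"].items()},
            seed=payload["seed"],
        )


@dataclass
class ParticleSample:
    """One Coulter-counter replicate: individual particle volumes plus the
    aliquot count used for the particles-per-µl arithmetic."""

    replicate_id: str
    volumes: np.ndarray  # µm³
    count_in_aliquot: int
    aliquot_volume: float = 50.0  # µl
    dilution_factor: float = 500.0

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        if v.size and np.any(v <= 0):
            raise ValueError("particle volumes must be positive")
        if self.count_in_aliquot < 0:
            raise ValueError("count_in_aliquot must be >= 0")
        self.volumes = v


# ---------------------------------------------------------------------------
# randomness plumbing


def _placement_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), 101])


def _noise_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), 202])


# ---------------------------------------------------------------------------
# sporulating-hypha movies


def _movie_midline(config: SimulationConfig) -> MidlineTrace:
    """Gently undulating midline spanning the hypha's final extent."""
    rows, cols = config.image_shape
    x0 = 10.0
    length_px = config.final_length / config.pixel_size
    x = np.arange(x0, x0 + length_px + 1e-9, 4.0)
    if x[-1] < x0 + length_px:
        x = np.append(x, x0 + length_px)
    y = rows / 2.0 + config.midline_wave_amp_px * np.sin(
        2.0 * np.pi * x / config.midline_wave_len_px
    )
    return MidlineTrace("h0", np.column_stack([x, y]), config.pixel_size)


def _check_canvas(config: SimulationConfig) -> None:
    rows, cols = config.image_shape
    needed_cols = 10.0 + config.final_length / config.pixel_size + 10.0
    needed_rows = (
        config.midline_wave_amp_px + config.hypha_width / config.pixel_size
    ) * 2 + 8
    if needed_cols > cols or needed_rows > rows:
        raise ValueError(
            f"image_shape {config.image_shape} too small for a hypha of final "
            f"length {config.final_length:.1f} µm; needs at least "
            f"({math.ceil(needed_rows)}, {math.ceil(needed_cols)}) px"
        )


def place_rings(config: SimulationConfig, rng: np.random.Generator) -> list[RingTruth]:
    """Place a ladder of rings in the tip compartment.

    Gaps are Gaussian around ``ring_spacing_mean``; onsets share a common
    post-cessation frame up to ±``ring_onset_jitter_frames``; per-ring
    mature amplitudes scatter lognormally around ``ring_amplitude`` with
    coefficient of variation ``ring_amplitude_cv`` (rings in one hypha are
    bright to different degrees).
    """
    zone_end = config.final_length - 0.7  # keep the distal ring off the tip
    zone_start = max(config.final_length - config.ring_zone_length, 1.0)
    base_onset = config.growth_cessation_frame + int(
        round(config.ring_onset_delay / config.frame_interval)
    )
    rise_frames = int(round(config.ring_rise_time / config.frame_interval))
    rings: list[RingTruth] = []
    pos = zone_start + config.ring_spacing_mean / 2.0
    while pos <= zone_end:
        jitter = (
            int(rng.integers(-config.ring_onset_jitter_frames,
                             config.ring_onset_jitter_frames + 1))
            if config.ring_onset_jitter_frames > 0
            else 0
        )
        onset = min(max(base_onset + jitter, 0), config.n_frames - 1)
        factor = (
            math.exp(rng.normal(0.0, config.ring_amplitude_cv))
            if config.ring_amplitude_cv > 0
            else 1.0
        )
        rings.append(
            RingTruth(
                arc_position=float(pos),
                onset_frame=onset,
                peak_frame=onset + rise_frames,
                amplitude=config.ring_amplitude * factor,
                axial_sigma=config.ring_axial_sigma,
            )
        )
        gap = rng.normal(config.ring_spacing_mean, config.ring_spacing_jitter)
        pos += max(gap, 0.3)  # physical lower bound on a gap
    return rings


def ring_intensity(ring: RingTruth, time_min: float, config: SimulationConfig) -> float:
    """Piecewise-linear rise/fall kinetic amplitude of one ring at a time point."""
    tau = time_min - ring.onset_frame * config.frame_interval
    if tau <= 0:
        return 0.0
    if tau < config.ring_rise_time:
        return ring.amplitude * tau / config.ring_rise_time
    tau -= config.ring_rise_time
    if tau < config.ring_fall_time:
        return ring.amplitude * (1.0 - tau / config.ring_fall_time)
    return 0.0


def _cyto_modulation(
    config: SimulationConfig, n_cols: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative modulation of the cytoplasmic level along the
    arc: exp of a Gaussian field with relative s.d. ``cyto_mod_cv`` and
    correlation length ``cyto_mod_corr`` µm."""
    if config.cyto_mod_cv == 0:
        return np.ones(n_cols)
    from scipy.ndimage import gaussian_filter1d

    white = rng.standard_normal(n_cols)
    smooth = gaussian_filter1d(
        white, sigma=config.cyto_mod_corr / config.pixel_size, mode="wrap"
    )
    sd = smooth.std()
    if sd == 0:
        return np.ones(n_cols)
    return np.exp(config.cyto_mod_cv * smooth / sd)


def render_movie(
    config: SimulationConfig,
    rings: list[RingTruth],
    midline: MidlineTrace,
    cyto_modulation: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless render of the growth + ring-ladder model onto the canvas."""
    rows, cols = config.image_shape
    r_idx = np.arange(rows, dtype=float)[:, None]
    c_idx = np.arange(cols, dtype=float)[None, :]
    x0 = 10.0
    px = config.pixel_size
    sigma_w_px = (config.hypha_width / 2.3548) / px
    y_c = rows / 2.0 + config.midline_wave_amp_px * np.sin(
        2.0 * np.pi * np.arange(cols) / config.midline_wave_len_px
    )
    ridge = np.exp(-0.5 * ((r_idx - y_c[None, :]) / sigma_w_px) ** 2)
    background = config.background_level + config.background_gradient * 0.5 * (
        r_idx + c_idx
    )
    # arc coordinate of each column measured along the midline polyline, so
    # ground-truth ring positions live in the same coordinate system the
    # straightening/profile chain measures
    pts = midline.points
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum_arc_um = np.concatenate([[0.0], np.cumsum(seg)]) * px
    c = np.arange(cols, dtype=float)
    arc_um = np.interp(c, pts[:, 0], cum_arc_um)
    left = c < pts[0, 0]
    arc_um[left] = (c[left] - pts[0, 0]) * px
    right = c > pts[-1, 0]
    arc_um[right] = cum_arc_um[-1] + (c[right] - pts[-1, 0]) * px
    if cyto_modulation is None:
        cyto_modulation = np.ones(cols)

    frames = np.empty((config.n_frames, rows, cols), dtype=float)
    for t in range(config.n_frames):
        time_min = t * config.frame_interval
        grown = min(t, config.growth_cessation_frame)
        length = config.initial_length + config.tip_rate * config.frame_interval * grown
        tip_col = x0 + length / px
        # soft tip and base edges (~1 px roll-off)
        axial = (
            config.cyto_level
            * cyto_modulation
            * expit(tip_col - np.arange(cols))
            * expit(np.arange(cols) - x0)
        )
        for ring in rings:
            amp = ring_intensity(ring, time_min, config)
            if amp > 0.0:
                axial = axial + amp * np.exp(
                    -0.5 * ((arc_um - ring.arc_position) / ring.axial_sigma) ** 2
                )
        if config.bleach_halflife is not None:
            axial = axial * 2.0 ** (-time_min / config.bleach_halflife)
        frames[t] = background + axial[None, :] * ridge
    return frames


def add_noise(
    frames: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Signal-dependent shot noise (Gaussian, var ∝ signal) + read noise."""
    shot = rng.standard_normal(frames.shape) * (
        config.shot_noise_scale * np.sqrt(np.clip(frames, 0.0, None))
    )
    read = rng.standard_normal(frames.shape) * config.read_noise_sigma
    return frames + shot + read


def simulate_movie(config: SimulationConfig) -> tuple[TimeLapseStack, GroundTruth]:
    """Simulate one sporulating hypha imaged in time lapse.

    Returns the (noisy) stack and the exact ground truth; the truth also
    carries the hypha midline so downstream profile extraction needs no
    manual tracing.
    """
    _check_canvas(config)
    rng_place = _placement_rng(config.seed)
    rng_noise = _noise_rng(config.seed)
    midline = _movie_midline(config)
    # placement draws are consumed even at zero amplitude so the noise stream
    # (and hence the rendered background) is unchanged by switching rings off
    rings = place_rings(config, rng_place)
    cyto_mod = _cyto_modulation(config, config.image_shape[1], rng_place)
    frames = render_movie(config, rings, midline, cyto_mod)
    frames = add_noise(frames, config, rng_noise)
    stack = TimeLapseStack(frames, config.frame_interval, config.pixel_size)
    truth = GroundTruth(
        rings=rings if config.ring_amplitude > 0 else [],
        hypha_lengths={"h0": config.final_length},
        midlines={"h0": midline.points.tolist()},
        seed=config.seed,
    )
    return stack, truth


def movie_midline_trace(truth: GroundTruth, config: SimulationConfig) -> MidlineTrace:
    """Reconstruct the MidlineTrace stored in a movie's ground truth."""
    pts = np.asarray(truth.midlines["h0"], dtype=float)
    return MidlineTrace("h0", pts, config.pixel_size)


# ---------------------------------------------------------------------------
# vegetative cross-wall snapshots


def _exponential_positions(
    length: float, mean_gap: float, rng: np.random.Generator
) -> list[float]:
    """Cross-wall arc positions: a Poisson process of rate 1/mean_gap on [0, L]."""
    if not math.isfinite(mean_gap):
        return []
    positions: list[float] = []
    pos = float(rng.exponential(mean_gap))
    while pos < length:
        positions.append(pos)
        pos += float(rng.exponential(mean_gap))
    return positions


def simulate_crosswall_field(
    config: SimulationConfig, n_hyphae: int
) -> tuple[PixelRaster, list[MidlineTrace], GroundTruth]:
    """Render ``n_hyphae`` septal-labelled vegetative hyphae as one snapshot.

    Hyphae are laid out as horizontal filaments in separate row bands; each
    gets a length drawn uniformly from ``config.hypha_length_range`` and
    cross-walls at i.i.d. exponential gaps with mean
    ``config.crosswall_spacing_mean`` (a Poisson process, so the expected
    count is length / mean gap with no edge bias).
    """
    if n_hyphae < 1:
        raise ValueError("n_hyphae must be >= 1")
    rng_place = _placement_rng(config.seed)
    rng_noise = _noise_rng(config.seed)
    px = config.pixel_size
    band = 16  # rows per hypha
    margin = 10.0
    lo, hi = config.hypha_length_range
    lengths = rng_place.uniform(lo, hi, size=n_hyphae)
    rows = band * n_hyphae
    cols = int(math.ceil(2 * margin + hi / px))

    sigma_w_px = (config.hypha_width / 2.3548) / px
    r_idx = np.arange(rows, dtype=float)[:, None]
    c_idx = np.arange(cols, dtype=float)
    arc_um = (c_idx - margin) * px
    # long snapshots emulate a stitched tiled acquisition: the planar
    # illumination gradient restarts every tile instead of accumulating
    # without bound along a canvas whose width scales with hyphal length
    tile = 512.0
    image = config.background_level + config.background_gradient * 0.5 * (
        r_idx + np.mod(c_idx, tile)[None, :]
    )

    midlines: list[MidlineTrace] = []
    truth = GroundTruth(seed=config.seed)
    for i in range(n_hyphae):
        hid = f"h{i}"
        length = float(lengths[i])
        positions = _exponential_positions(
            length, config.crosswall_spacing_mean, rng_place
        )
        y_mid = band * i + band / 2.0
        cyto_mod = _cyto_modulation(config, cols, rng_place)
        axial = (
            config.cyto_level
            * cyto_mod
            * expit((margin + length / px) - c_idx)
            * expit(c_idx - margin)
        )
        for p in positions:
            axial = axial + config.ring_amplitude * np.exp(
                -0.5 * ((arc_um - p) / config.crosswall_sigma) ** 2
            )
        ridge = np.exp(-0.5 * ((r_idx - y_mid) / sigma_w_px) ** 2)
        image = image + axial[None, :] * ridge

        xs = np.arange(margin, margin + length / px + 1e-9, 4.0)
        if xs[-1] < margin + length / px:
            xs = np.append(xs, margin + length / px)
        pts = np.column_stack([xs, np.full_like(xs, y_mid)])
        midlines.append(MidlineTrace(hid, pts, px))
        truth.hypha_lengths[hid] = length
        truth.midlines[hid] = pts.tolist()
        for p in sorted(positions):
            truth.crosswalls.append(CrosswallTruth(hid, float(p)))

    image = add_noise(image[None, :, :], config, rng_noise)[0]
    return PixelRaster(image, px), midlines, truth


# ---------------------------------------------------------------------------
# particle-volume samples


def simulate_particle_volumes(
    log_mean: float,
    log_sd: float,
    n: int,
    seed: int,
    replicate_id: str = "r1",
    aliquot_volume: float = 50.0,
    dilution_factor: float = 500.0,
) -> ParticleSample:
    """Draw ``n`` particle volumes (µm³) log-normally; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng([int(seed) % (2**31), 303])
    volumes = np.exp(rng.normal(log_mean, log_sd, size=n))
    return ParticleSample(
        replicate_id=replicate_id,
        volumes=volumes,
        count_in_aliquot=n,
        aliquot_volume=aliquot_volume,
        dilution_factor=dilution_factor,
    )


# ---------------------------------------------------------------------------
# evaluation helpers (used by tests and acceptance checks)


def match_positions(
    detected: list[float] | np.ndarray,
    truth: list[float] | np.ndarray,
    tol: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true positions within ``tol``.

    Returns (true positives, false positives, false negatives).
    """
    detected = sorted(float(d) for d in detected)
    remaining = sorted(float(t) for t in truth)
    tp = 0
    fp = 0
    for d in detected:
        if remaining:
            j = int(np.argmin([abs(d - t) for t in remaining]))
            if abs(d - remaining[j]) <= tol:
                remaining.pop(j)
                tp += 1
                continue
        fp += 1
    return tp, fp, len(remaining)
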