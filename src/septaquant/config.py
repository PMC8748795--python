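"""Simulation configuration: schema, validation, presets, YAML round-trip.

The presets encode the two imaging phenotypes the downstream analyses
contrast: "wt_like" hyphae assemble bright, tight, fast-rising septal rings;
"mutant_like" hyphae assemble dimmer, 10% wider, slower-rising rings. The two
presets differ ONLY in ``ring_amplitude``, ``ring_axial_sigma`` and
``ring_rise_time`` so that any downstream difference is attributable to those
three parameters. "no_septa" switches vegetative cross-wall formation off
entirely (infinite mean gap).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class SimulationConfig:
    # imaging geometry / acquisition
    pixel_size: float = 0.1  # µm/px
    frame_interval: float = 10.0  # min/frame
    n_frames: int = 24
    image_shape: tuple[int, int] = (48, 420)  # (rows, cols) px

    # hypha geometry and growth
    hypha_width: float = 0.8  # µm, full width (FWHM of the transverse ridge)
    initial_length: float = 28.0  # µm at frame 0
    tip_rate: float = 0.3  # µm/min while growing
    growth_cessation_frame: int = 1  # growth stops at this frame index
    midline_wave_amp_px: float = 2.0  # gentle midline undulation
    midline_wave_len_px: float = 250.0

    # septal ring placement and kinetics
    ring_spacing_mean: float = 1.3  # µm between neighbouring rings
    ring_spacing_jitter: float = 0.15  # µm s.d. on the gaps
    ring_zone_length: float = 10.0  # µm of sporogenic tip compartment
    ring_axial_sigma: float = 0.20  # µm, axial Gaussian s.d. of a band
    ring_amplitude: float = 800.0  # AU apex above cytoplasm at full maturity
    ring_rise_time: float = 40.0  # min, assembly to peak
    ring_fall_time: float = 80.0  # min, disassembly
    ring_onset_delay: float = 20.0  # min after growth cessation
    ring_onset_jitter_frames: int = 1  # per-ring onset jitter (frames)

    # vegetative cross-walls
    crosswall_spacing_mean: float = 25.0  # µm mean inter-septum gap; inf = none
    crosswall_sigma: float = 0.15  # µm axial s.d. of a labelled septum
    hypha_length_range: tuple[float, float] = (50.0, 500.0)  # µm, vegetative

    # fluorescence model
    # kept below the 100 AU ring filter: cytoplasmic signal is sub-threshold
    cyto_level: float = 60.0  # AU cytoplasmic baseline on the ridge
    # biological heterogeneity: ring-to-ring brightness spread and smooth
    # axial variation of cytoplasmic fluorescence along the hypha
    ring_amplitude_cv: float = 0.15  # lognormal CV of per-ring amplitude
    cyto_mod_cv: float = 0.10  # relative s.d. of axial cytoplasm modulation
    cyto_mod_corr: float = 3.0  # µm correlation length of the modulation
    background_level: float = 20.0  # AU
    background_gradient: float = 0.02  # AU/px planar tilt
    shot_noise_scale: float = 0.5  # s.d. = scale * sqrt(signal)
    read_noise_sigma: float = 3.0  # AU additive Gaussian
    bleach_halflife: float | None = None  # min; None disables bleaching

    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "hypha_width": self.hypha_width,
            "initial_length": self.initial_length,
            "tip_rate": self.tip_rate,
            "ring_spacing_mean": self.ring_spacing_mean,
            "ring_zone_length": self.ring_zone_length,
            "ring_axial_sigma": self.ring_axial_sigma,
            "ring_rise_time": self.ring_rise_time,
            "ring_fall_time": self.ring_fall_time,
            "crosswall_spacing_mean": self.crosswall_spacing_mean,
            "crosswall_sigma": self.crosswall_sigma,
            "cyto_level": self.cyto_level,
            "cyto_mod_corr": self.cyto_mod_corr,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name, value in {
            "ring_amplitude": self.ring_amplitude,
            "ring_spacing_jitter": self.ring_spacing_jitter,
            "background_level": self.background_level,
            "background_gradient": self.background_gradient,
            "shot_noise_scale": self.shot_noise_scale,
            "read_noise_sigma": self.read_noise_sigma,
            "ring_onset_delay": self.ring_onset_delay,
            "ring_amplitude_cv": self.ring_amplitude_cv,
            "cyto_mod_cv": self.cyto_mod_cv,
        }.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.ring_spacing_jitter >= self.ring_spacing_mean:
            raise ValueError("ring_spacing_jitter must be < ring_spacing_mean")
        if self.bleach_halflife is not None and self.bleach_halflife <= 0:
            raise ValueError("bleach_halflife must be positive or None")
        lo, hi = self.hypha_length_range
        if not (0 < lo <= hi):
            raise ValueError("hypha_length_range must satisfy 0 < lo <= hi")
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError("image_shape too small")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def final_length(self) -> float:
        """Hyphal arc length (µm) after growth stops."""
        return self.initial_length + self.tip_rate * self.frame_interval * (
            self.growth_cessation_frame
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["hypha_length_range"] = list(self.hypha_length_range)
        return d


_PRESET_OVERRIDES: dict[str, dict] = {
    # the WT-like phenotype is the dataclass default
    "wt_like": {},
    # dimmer, 10% wider, slower-assembling rings
    "mutant_like": {
        "ring_amplitude": 500.0,
        "ring_axial_sigma": 0.22,
        "ring_rise_time": 90.0,
    },
    # vegetative mycelium devoid of cross-walls
    "no_septa": {"crosswall_spacing_mean": math.inf},
    # constitutive-expression regime: doubled cross-wall frequency
    "double_septa": {"crosswall_spacing_mean": 12.5},
}

PRESET_NAMES = tuple(_PRESET_OVERRIDES)


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Return a named preset configuration, optionally overridden field-wise."""
    if name not in _PRESET_OVERRIDES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kwargs = dict(_PRESET_OVERRIDES[name])
    kwargs.update(overrides)
    kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: str) -> SimulationConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "image_shape" in raw:
        raw["image_shape"] = tuple(raw["image_shape"])
    if "hypha_length_range" in raw:
        raw["hypha_length_range"] = tuple(raw["hypha_length_range"])
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
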