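import numpy as np
import pytest

from septaquant import PixelRaster, preset


@pytest.fixture
def wt_config():
    return preset("wt_like", seed=1)


@pytest.fixture
def tiny_config():
    """A small, fast movie configuration for geometry-level tests."""
    return preset(
        "wt_like",
        seed=1,
        image_shape=(40, 260),
        initial_length=18.0,
        ring_zone_length=6.0,
    )


@pytest.fixture
def constant_raster():
    return PixelRaster(np.full((20, 30), 7.0), pixel_size=0.1)


def make_profile_array(
    n: int, rng: np.random.Generator, quantize: bool = True
) -> np.ndarray:
    """Random test profile: smooth bumps + noise, optionally quantized so
    that exact ties and plateaus occur."""
    x = np.arange(n)
    y = np.zeros(n, dtype=float)
    for _ in range(rng.integers(0, 4)):
        c = rng.uniform(0, n)
        a = rng.uniform(20, 300)
        s = rng.uniform(1, 6)
        y += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    y += rng.normal(0, rng.uniform(0, 30), size=n)
    y = np.clip(y, 0, None)
    if quantize:
        y = np.round(y / rng.choice([1, 5, 25])) * 1.0
    return y
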