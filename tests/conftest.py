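import dataclasses

import numpy as np
import pytest

from phagoquant import synthgen


@pytest.fixture(scope="session")
def small_config() -> synthgen.ImagingSimConfig:
    """A compact field: fast to render, still multi-cell."""
    return synthgen.ImagingSimConfig(
        field_shape=(256, 256), n_nuclei=8, n_decoys=4, rng_seed=42
    )


@pytest.fixture(scope="session")
def noise_free_field(small_config):
    cfg = small_config.without_noise()
    return synthgen.simulate_field(cfg, "isogenic", 135.0)


def rasterize_ellipse(shape, center, a, b, theta):
    """Axis convention: major axis along (cos theta, sin theta) in (row, col)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def cross_mask(size=81, arm=7, length=60):
    m = np.zeros((size, size), dtype=bool)
    c = size // 2
    m[c - arm : c + arm + 1, c - length // 2 : c + length // 2 + 1] = True
    m[c - length // 2 : c + length // 2 + 1, c - arm : c + arm + 1] = True
    return m
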