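import numpy as np
import pytest

from guvmem import (
    DetectParams,
    PipelineParams,
    generate_guv_scene,
    random_scene_spec,
)


@pytest.fixture
def pipeline_params():
    return PipelineParams()


@pytest.fixture
def detect_params():
    return DetectParams(r_min=8, r_max=16)


@pytest.fixture
def noiseless_scene():
    """A deterministic noiseless 10-GUV scene with planted puncta on 7 GUVs."""
    spec = random_scene_spec(seed=11, noise_sigma=0.0)
    return generate_guv_scene(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def spot_crop(shape=(34, 34), center=(17, 20), amplitude=200.0, sigma=1.5,
              background=100.0, noise_sigma=0.0, seed=0):
    """A single-Gaussian-spot crop used across puncta tests."""
    rows, cols = np.mgrid[0: shape[0], 0: shape[1]].astype(float)
    img = background + amplitude * np.exp(
        -(((rows - center[0]) ** 2 + (cols - center[1]) ** 2)) / (2 * sigma**2)
    )
    if noise_sigma > 0:
        img = img + np.random.default_rng(seed).normal(0, noise_sigma, shape)
    return np.clip(img, 0, 65535)
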