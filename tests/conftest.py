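import logging

import numpy as np
import pytest
from scipy import ndimage

from colonyflow import GrayFrame, PipelineConfig, SceneSpec, generate_scene
from colonyflow.synthetic import regular_polygon

logging.getLogger("colonyflow").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_frame_pair():
    """Smoothed random texture and its (v=2, u=3) rigid translation."""
    r = np.random.default_rng(0)
    tex = ndimage.gaussian_filter(r.random((128, 128)), 2)
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    moved = np.roll(np.roll(tex, 2, axis=0), 3, axis=1)
    return GrayFrame(tex, 0), GrayFrame(moved, 1)


@pytest.fixture
def small_scene():
    """One small static colony scene with ground truth."""
    spec = SceneSpec(
        shape=(256, 256),
        colony_polygon=regular_polygon((128, 128), 80.0, 8),
        cell_size_px=24.0,
        n_feeder=6,
        n_decoys=4,
        noise_sd=0.01,
        seed=1,
    )
    frames, truth = generate_scene(spec)
    return frames, truth


@pytest.fixture
def small_config():
    """Config scaled to 256-px test scenes (bandwidth shrunk accordingly)."""
    return PipelineConfig(kde_bandwidth=30.0, kde_threshold_frac=0.3)
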