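"""Shared fixtures: small render geometry and the session-scoped trained model."""

from __future__ import annotations

import numpy as np
import pytest

import canopymass as cm
from canopymass.benchmark import (
    BENCH_CROP,
    BENCH_IMAGE_SIZE,
    BENCH_MM_PER_PIXEL,
    train_fusion_benchmark,
)

# small render geometry shared by fast unit tests
SMALL_KW = dict(image_size=BENCH_IMAGE_SIZE, mm_per_pixel=BENCH_MM_PER_PIXEL)
SMALL_CROP = BENCH_CROP


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_sample(rng):
    """One rendered occluded-neighborhood sample at reduced resolution."""
    scene, cid = cm.scene.make_neighborhood_scene(rng, 6.0, **SMALL_KW)
    return cm.render_scene(scene, cid, rng)


@pytest.fixture(scope="session")
def trained_benchmark():
    """The reduced-scale fusion model trained once per session on ~500
    synthetic scenes (two-stage protocol); shared by the parameter-recovery,
    localization, and robustness tests."""
    return train_fusion_benchmark(seed=11, keep_datasets=True)
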