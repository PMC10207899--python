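"""Shared fixtures: deterministic synthetic scenes and reduced-width models.

The scene fixture pack is a frozen list of seeds rendered at 96x96 by
the deterministic generator at test time, so no image files need to be
stored.
"""

import numpy as np
import pytest

from rootseg.backbone import BackboneConfig
from rootseg.ocr import ModelConfig, RootSegmenter
from rootseg.presets import smoke
from rootseg.synthetic import SceneSpec, generate_scene

FIXTURE_SEEDS = (11, 23, 37, 51, 68, 79)


@pytest.fixture(scope="session")
def fixture_spec() -> SceneSpec:
    return SceneSpec(width=96, height=96, n_roots=2,
                     root_width_range=(2.0, 6.0), step_length=4.0,
                     n_stones=2, n_cracks=1, n_film_patches=0, n_worms=1)


@pytest.fixture(scope="session")
def fixture_scenes(fixture_spec):
    """Six small deterministic scenes (the committed fixture pack)."""
    return [generate_scene(fixture_spec, s) for s in FIXTURE_SEEDS]


@pytest.fixture(scope="session")
def tiny_model() -> RootSegmenter:
    """A width-8 improved model, cheap enough for forward-pass tests."""
    preset = smoke()
    return RootSegmenter(preset.backbone, preset.model, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
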