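"""Shared fixtures: small synthetic sessions and rendered silhouettes."""

from __future__ import annotations

import numpy as np
import pytest

from momofuse.synthetic import (
    GeneratorConfig,
    generate_session,
    make_background,
    render_stick_figure,
    stick_figure_joints,
    _class_params,
)


@pytest.fixture(scope="session")
def small_session():
    """A compact 3-class session exercising every modality."""
    cfg = GeneratorConfig(
        n_classes=3, segments_per_class=1, frame_fs=5.0,
        frame_size=(160, 120), seed=11,
    )
    rec, truth = generate_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def rendered_figure():
    """One stick-figure mask + frame with its ground-truth joints."""
    params = _class_params(3, 6)
    background = make_background((320, 240), seed=5)
    joints = stick_figure_joints(1.7, params, 160.0, (320, 240))
    mask, frame = render_stick_figure(joints, (320, 240), background)
    return joints, mask, frame, background


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
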