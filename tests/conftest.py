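"""Shared fixtures.

The heavy session fixtures simulate one desk-scale dual-probe scene and push
it through the pipeline stages once; registration, tracking, strain and
metric tests all reuse them.  Unit tests build their own tiny scenes.
"""

import numpy as np
import pytest

from aortaus.pipeline import (
    PipelineConfig,
    RunState,
    stage_beamform,
    stage_metrics,
    stage_simulate,
    stage_strain,
    stage_track,
)


def standard_config() -> PipelineConfig:
    """The study conditions: 64 elements/probe, 5 steering angles,
    ~5,000 scatterers, noiseless, 2% peak inner-radius excursion."""
    cfg = PipelineConfig()
    cfg.mode = "both"
    cfg.seed = 7
    return cfg


@pytest.fixture(scope="session")
def scene_state():
    """Standard phantom simulated and beamformed (shared, read-only)."""
    state = RunState(config=standard_config())
    state = stage_simulate(state)
    state = stage_beamform(state)
    return state


@pytest.fixture(scope="session")
def tracked_state(scene_state):
    """Standard phantom tracked through strain and metrics in both modes."""
    state = stage_track(scene_state)
    state = stage_strain(state)
    state = stage_metrics(state)
    return state


@pytest.fixture(scope="session")
def tiny_scene_config() -> PipelineConfig:
    """A seconds-scale scene for optimizer/pipeline mechanics tests."""
    cfg = PipelineConfig()
    cfg.seed = 3
    cfg.scene.n_elements = 24
    cfg.scene.steering_angles = (-6.0, 6.0)
    cfg.scene.n_frames = 2
    cfg.scene.phantom.wall_density = 6.0
    cfg.scene.phantom.background_density = 0.3
    cfg.scene.phantom.x_extent = (-15.0, 15.0)
    cfg.scene.phantom.z_extent = (25.0, 55.0)
    cfg.grids.roi_radius = 13.0
    cfg.registration.roi_half = 10.0
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
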