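from dataclasses import dataclass

import numpy as np
import pytest

from gatedpet import phantom, pipeline


@dataclass
class PhantomRun:
    config: phantom.PhantomConfig
    dynamic: phantom.DynamicFrameSequence
    gated: object
    truth: phantom.GroundTruth
    analysis: pipeline.GatedAnalysis


def _run(config: phantom.PhantomConfig) -> PhantomRun:
    dyn, gated, truth = phantom.render(config)
    analysis = pipeline.analyze_gated(gated, phantom.default_planes(config))
    return PhantomRun(config, dyn, gated, truth, analysis)


@pytest.fixture(scope="session")
def small_config() -> phantom.PhantomConfig:
    """Coarse phantom (same field of view, 2x voxel) for fast unit tests."""
    return phantom.PhantomConfig(
        grid_shape=(32, 32, 24), voxel_size_mm=6.54, poisson_noise=False
    )


@pytest.fixture(scope="session")
def small_run(small_config) -> PhantomRun:
    return _run(small_config)


@pytest.fixture(scope="session")
def full_noiseless_run() -> PhantomRun:
    """Acquisition-scale noiseless phantom analysed end to end."""
    return _run(phantom.PhantomConfig(poisson_noise=False))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
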