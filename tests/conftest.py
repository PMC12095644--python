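"""Shared fixtures: synthetic images and (expensive) fitted pipelines.

Session scope keeps the 20-image standard suite and its pipeline fits
computed once for the whole run.
"""

import numpy as np
import pytest

from flowseg import (
    FixtureSpec,
    PipelineConfig,
    SelfSupervisedSegmenter,
    generate_fixture,
    generate_suite,
)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def fixture_default():
    """One default-spec synthetic image with exact ground truth."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def fitted_default(fixture_default, default_config):
    """Full pipeline fit of the default fixture."""
    return SelfSupervisedSegmenter(fixture_default.image, default_config).fit()


@pytest.fixture(scope="session")
def suite():
    """The standard 20-image fixture suite plus variants."""
    return generate_suite(0)


@pytest.fixture(scope="session")
def suite_results(suite, default_config):
    """(fixture, result) pairs for every sparse suite image."""
    return [
        (fx, SelfSupervisedSegmenter(fx.image, default_config).fit())
        for fx in suite["sparse"]
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
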