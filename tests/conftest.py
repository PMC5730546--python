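import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from daphtox.detection import ImagingConfig
from daphtox.simulator import (
    ChamberSpec,
    LocomotionParams,
    render_clip,
    sample_separated_trajectories,
)


@pytest.fixture(scope="session")
def chamber() -> ChamberSpec:
    return ChamberSpec()


@pytest.fixture(scope="session")
def params() -> LocomotionParams:
    return LocomotionParams()


@pytest.fixture(scope="session")
def imaging(chamber) -> ImagingConfig:
    return ImagingConfig(mm_per_px=chamber.mm_per_px, fps=30.0)


@pytest.fixture(scope="session")
def lane_clip(chamber, params):
    """Rendered 10 s clip of 5 lane-separated animals (no occlusions)."""
    truths = sample_separated_trajectories(
        5, params, chamber, duration_s=10.0, fps=30.0, seed=42
    )
    clip = render_clip(truths, chamber, fps=30.0, noise_sd=2.0, blur_px=1.0, seed=7)
    return clip


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
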