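import numpy as np
import pytest
from hypothesis import settings

from chickvision.stimuli import GrayImage, ViewpointSpec, default_objects, render_viewpoint
from chickvision.synthetic_behavior import CohortParams, simulate_trials

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def objects():
    return default_objects()


@pytest.fixture(scope="session")
def frontal_images(objects):
    o1, o2 = objects
    return (
        render_viewpoint(o1, ViewpointSpec(0.0, 0.0), 128),
        render_viewpoint(o2, ViewpointSpec(0.0, 0.0), 128),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A default synthetic cohort (10 subjects x 7 days x 27 ranges)."""
    return simulate_trials(CohortParams(seed=11))


def grating(theta_deg: float, size: int = 96, wavelength: float = 8.0,
            phase: float = 0.0) -> GrayImage:
    """Sinusoidal luminance grating fixture."""
    ax = np.arange(size)
    X, Y = np.meshgrid(ax, ax)
    t = np.deg2rad(theta_deg)
    v = 0.5 + 0.45 * np.sin(
        2.0 * np.pi * (X * np.cos(t) + Y * np.sin(t)) / wavelength + phase
    )
    return GrayImage(np.clip(v, 0.0, 1.0))
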