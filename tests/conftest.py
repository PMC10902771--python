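import pytest
from hypothesis import HealthCheck, settings

from headcirc.phantom import PhantomSpec, render_phantom

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, clutter-free phantom with its ground truth."""
    spec = PhantomSpec(noise_sd=0.0, clutter_count=0, seed=1)
    img, gt = render_phantom(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def cluttered_phantom():
    """Same head as clean_phantom but with 5 distractor polygons."""
    spec = PhantomSpec(noise_sd=0.0, clutter_count=5, seed=1)
    img, gt = render_phantom(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with pixel noise, clutter and a slight out-of-plane tilt."""
    spec = PhantomSpec(noise_sd=5.0, clutter_count=3, seed=7, foreshorten=0.98)
    img, gt = render_phantom(spec)
    return spec, img, gt
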