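import numpy as np
import pytest

from thermosih.synthetic import PhantomSpec, random_phantom, render_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def clean_phantom():
    """A noise-free, texture-free phantom with its ground truth."""
    rng = np.random.default_rng(11)
    spec = random_phantom(rng, texture_amplitude=0.0, sensor_noise_sd=0.0)
    frame, truth = render_phantom(spec, rng)
    return spec, frame, truth


def make_phantom(seed, **overrides):
    """Helper: random pose rendered with a private rng."""
    rng = np.random.default_rng(seed)
    spec = random_phantom(rng, **overrides)
    return spec, *render_phantom(spec, rng)
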