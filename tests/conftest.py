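import numpy as np
import pytest

from nodulescan import CtSlice, NoduleSpec, PhantomSpec, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_slice():
    """One default phantom slice with a mixed set of nodules."""
    spec = PhantomSpec(
        nodules=[
            NoduleSpec(diameter_mm=12.0, attachment="isolated"),
            NoduleSpec(diameter_mm=18.0, attachment="juxtapleural"),
            NoduleSpec(diameter_mm=10.0, attachment="juxtavascular"),
        ],
        seed=7,
    )
    return generate_slice(spec)


@pytest.fixture(scope="session")
def clean_phantom_slice():
    """Noise-free phantom with two isolated nodules (geometry checks)."""
    spec = PhantomSpec(
        nodules=[
            NoduleSpec(diameter_mm=10.0, attachment="isolated"),
            NoduleSpec(diameter_mm=20.0, attachment="isolated"),
        ],
        noise_sigma=0.0,
        seed=3,
    )
    return generate_slice(spec)


def make_slice(pixels, spacing=(0.6, 0.6), id="test"):
    return CtSlice(pixels=np.asarray(pixels, dtype=float), spacing_mm=spacing, id=id)
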