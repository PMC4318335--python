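import pytest

from myeloarch import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def slab_phantom():
    """Noise-free, bias-free parallel slab at 0.7 mm (t=4.5, d=1.5)."""
    return make_phantom(PhantomSpec(geometry="slab", shape=(48, 40, 40), seed=11))


@pytest.fixture(scope="session")
def shell_phantom():
    """Noise-free concentric spherical shell at 0.7 mm (t=4.5, d=1.5)."""
    return make_phantom(
        PhantomSpec(geometry="spherical_shell", shape=(36, 36, 36), seed=12)
    )


@pytest.fixture(scope="session")
def biased_phantom():
    """Noise-free slab with a shared multiplicative bias of amplitude 0.3."""
    return make_phantom(
        PhantomSpec(geometry="slab", shape=(48, 40, 40), bias_amplitude=0.3, seed=13)
    )
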