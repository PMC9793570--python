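import numpy as np
import pytest

from hepavol import BinaryMask, CTVolume, PhantomSpec, generate_phantom


def random_mask(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(rng.random(shape) < p, spacing)


@pytest.fixture(scope="session")
def small_phantom():
    """A quiet desk-scale phantom with a moderate lesion burden."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 24),
        spacing_mm=(2.0, 2.0, 5.0),
        liver_semiaxes_mm=(36.0, 30.0, 40.0),
        target_lpdi_pct=10.0,
        lesion_count=2,
        noise_sd=0.0,
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(
        grid_shape=(48, 48, 24),
        spacing_mm=(2.0, 2.0, 5.0),
        liver_semiaxes_mm=(36.0, 30.0, 40.0),
        target_lpdi_pct=15.0,
        lesion_count=3,
        noise_sd=5.0,
        seed=9,
    )
    return generate_phantom(spec)
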