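import numpy as np
import pytest

from thromboseg import PatientStudy, PhantomParams, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_study(rng):
    """Hand-built 4-slice study with nonempty masks, 12x12."""
    slices, masks = [], []
    for i in range(4):
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        msk = np.zeros((12, 12), dtype=np.uint8)
        msk[4 : 7 + i % 2, 5:8] = 1
        slices.append(img)
        masks.append(msk)
    return PatientStudy("tiny", slices, masks, pixel_spacing=0.8)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, fully separable phantom: the easiest study condition."""
    params = PhantomParams(noise_sigma=0.0, tissue_overlap=0.0, stent_artifact=False, seed=3)
    return generate_study(params), params


def random_binary_mask(rng, shape=(16, 16), p=0.3, nonempty=False):
    m = (rng.random(shape) < p).astype(np.uint8)
    if nonempty and not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = 1
    return m
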