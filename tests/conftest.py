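import numpy as np
import pytest

from macaqueid import imaging, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """Four synthetic identities, fixed seed, shared across tests."""
    return synth.make_population(4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_population):
    """4 identities x 12 images, preprocessed to canonical grayscale."""
    ds = synth.make_dataset(small_population, images_per_id=12, seed=11)
    grays = [imaging.preprocess(im) for im in ds.images]
    return grays, list(ds.labels)


@pytest.fixture(scope="session")
def tiny_gray_images():
    """Fifty 20x15 images from a 3-factor linear model plus small noise."""
    r = np.random.default_rng(77)
    factors = r.normal(size=(3, 20 * 15)) * 40
    coeffs = r.normal(size=(50, 3))
    X = 128 + coeffs @ factors + r.normal(scale=2.0, size=(50, 20 * 15))
    return [x.reshape(20, 15) for x in np.clip(X, 0, 255)]
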