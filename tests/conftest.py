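import numpy as np
import pytest

from skinaudit.synthetic import SyntheticSpec, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dataset200():
    """The standard end-to-end fixture: 200 mixed images, fixed seed."""
    return gen_dataset(SyntheticSpec(seed=11, n_images=200))


@pytest.fixture(scope="session")
def skin_subset(dataset200):
    """Masked skin images with binary tone labels (1 = FST V-VI)."""
    images, masks, y = [], [], []
    for img, m, t in zip(dataset200.images, dataset200.masks,
                         dataset200.tone_labels):
        if t is None:
            continue
        images.append(img)
        masks.append(m)
        y.append(1 if t == "V-VI" else 0)
    return images, masks, np.array(y)


def random_patch(rng, h=8, w=8):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
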