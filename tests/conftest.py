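import numpy as np
import pytest

from fusionacl import phantom


@pytest.fixture(scope="session")
def small_dataset():
    """Forty quick sagittal phantoms with a clear lesion, both tasks mixed."""
    cfg = phantom.PhantomConfig(
        image_size=64, plane="sagittal", acl_tear_prob=0.5,
        meniscus_tear_prob=0.5, lesion_contrast=0.5, noise_sd=0.02,
        n_images=40, seed=123,
    )
    return phantom.generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
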