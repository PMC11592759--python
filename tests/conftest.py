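import numpy as np
import pytest

from tumorscope import PhantomConfig, generate_phantom_case, generate_phantom_dataset


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(image_size=32, n_slices=4,
                         lung_fraction_range=(0.05, 0.15),
                         n_nodules_range=(1, 2),
                         nodule_radius_range=(1.5, 2.5),
                         noise_sd=0.03, seed=7)


@pytest.fixture(scope="session")
def small_case(small_config):
    return generate_phantom_case(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_phantom_dataset(small_config, 6, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
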