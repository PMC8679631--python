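import numpy as np
import pytest

from fltpet.simulate import PhantomConfig, build_aif, generate_phantom


@pytest.fixture(scope="session")
def phantom_cfg():
    return PhantomConfig()


@pytest.fixture(scope="session")
def default_phantom(phantom_cfg):
    """Seeded default phantom (noisy series + ground truth)."""
    return generate_phantom(phantom_cfg)


@pytest.fixture(scope="session")
def noise_free_phantom(phantom_cfg):
    from dataclasses import replace

    return generate_phantom(replace(phantom_cfg, noise_coeff=0.0))


@pytest.fixture(scope="session")
def default_aif(phantom_cfg):
    return build_aif(phantom_cfg)


@pytest.fixture(scope="session")
def default_schedule(phantom_cfg):
    return phantom_cfg.schedule


@pytest.fixture()
def rng():
    return np.random.default_rng(20200101)
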