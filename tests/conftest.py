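import numpy as np
import pytest

import medcss as m


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_splits():
    """Small nodule phantom splits shared by fast pipeline tests."""
    spec = m.PhantomSpec(family="nodule", n=48, side=12, positive_fraction=0.3,
                         noise_sd=0.02, blur_sd=0.5, seed=7)
    return m.generate_phantom_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return m.ModelConfig(depth=10, num_classes=2, base_width=8, proj_dim=8,
                         se_reduction=4, task="binary")


@pytest.fixture(scope="session")
def tiny_model(tiny_model_cfg):
    return m.build_model(tiny_model_cfg, seed=0)
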