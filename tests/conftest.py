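import numpy as np
import pytest

from safnet.io_preprocess import PreprocessSpec, preprocess
from safnet.model import SAFNet, SAFNetConfig
from safnet.phantom import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def desk_model_cfg() -> SAFNetConfig:
    return SAFNetConfig.desk_scale(num_classes=6)


@pytest.fixture(scope="session")
def desk_model(desk_model_cfg) -> SAFNet:
    return SAFNet(desk_model_cfg, seed=0)


@pytest.fixture(scope="session")
def desk_phantom_cfg() -> PhantomConfig:
    return PhantomConfig.desk_scale()


@pytest.fixture(scope="session")
def desk_data(desk_phantom_cfg):
    """Three preprocessed desk-scale phantoms keyed by id."""
    samples = generate_dataset(3, desk_phantom_cfg, master_seed=1)
    spec = PreprocessSpec(target_shape=desk_phantom_cfg.shape,
                          crop_width_fraction=1.0)
    return {s.sample_id: preprocess(s, spec) for s in samples}


@pytest.fixture(scope="session")
def micro_phantom_cfg() -> PhantomConfig:
    """Smallest phantom that still has alternating structures (4 classes)."""
    return PhantomConfig(shape=(8, 32, 16), n_vertebrae=2, n_discs=1,
                         vertebra_height_frac=0.18, disc_height_frac=0.07)


@pytest.fixture(scope="session")
def micro_model_cfg() -> SAFNetConfig:
    return SAFNetConfig(base_channels=16, num_classes=4, input_shape=(8, 32, 16))


@pytest.fixture(scope="session")
def micro_data(micro_phantom_cfg):
    samples = generate_dataset(4, micro_phantom_cfg, master_seed=2)
    spec = PreprocessSpec(target_shape=micro_phantom_cfg.shape,
                          crop_width_fraction=1.0)
    return {s.sample_id: preprocess(s, spec) for s in samples}
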