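import numpy as np
import pytest

from saen.bayesian_unet import UNetConfig
from saen.phantom import PhantomConfig, generate_dataset
from saen.training import TrainConfig, records_from_phantoms


@pytest.fixture(scope="session")
def small_phantom_cfg() -> PhantomConfig:
    """32x32 phantoms with one sharp and one blurry lesion."""
    return PhantomConfig(image_height=32, image_width=32, n_periventricular=1,
                         n_deep=1, lesion_radius_range=(2.0, 4.0),
                         annotation_jitter_sigma=1.5)


@pytest.fixture(scope="session")
def small_dataset(small_phantom_cfg):
    return generate_dataset(small_phantom_cfg, 8, seed=11)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return records_from_phantoms(small_dataset)


@pytest.fixture(scope="session")
def tiny_unet_cfg() -> UNetConfig:
    return UNetConfig(in_channels=2, n_classes=2, depth=3, base_filters=4,
                      dropout_rate=0.0)


@pytest.fixture(scope="session")
def tiny_oracle_cfg() -> UNetConfig:
    return UNetConfig(in_channels=2, n_classes=2, depth=3, base_filters=4,
                      dropout_rate=0.5, dropout_mode="train_and_inference")


@pytest.fixture(scope="session")
def tiny_train_cfg() -> TrainConfig:
    return TrainConfig(epochs=2, crops_per_image=4, patch_shape=(16, 16), seed=3)


@pytest.fixture(scope="session")
def trained_tiny_model(small_records, tiny_unet_cfg, tiny_train_cfg):
    from saen.training import train_base_model

    return train_base_model(small_records, None, tiny_unet_cfg, tiny_train_cfg,
                            lambda_used=1.0)


@pytest.fixture(scope="session")
def trained_tiny_oracle(small_records, tiny_oracle_cfg, tiny_train_cfg):
    from saen.training import train_uncertainty_oracle

    return train_uncertainty_oracle(small_records, tiny_oracle_cfg, tiny_train_cfg)


def random_probability_stack(rng: np.random.Generator, T: int, h: int = 6,
                             w: int = 6, classes: int = 2) -> np.ndarray:
    """Random softmax samples (T, classes, h, w) summing to 1 per pixel."""
    raw = rng.random((T, classes, h, w))
    return raw / raw.sum(axis=1, keepdims=True)
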