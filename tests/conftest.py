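"""Shared fixtures: small synthetic datasets and once-trained extractors."""

import numpy as np
import pytest

import brainfuse as bf


@pytest.fixture(scope="session")
def modality_images():
    """100 synthetic modality slices (25 per class) at 32x32."""
    return bf.make_modality_images(25, 32, 32, seed=7)


@pytest.fixture(scope="session")
def trained_resnet(modality_images):
    """Scaled-down modified ResNet-50 trained once for the whole suite."""
    ext = bf.ResNetFeatureExtractor(width_scale=0.25, max_epochs=4,
                                    minibatch=32, learning_rate=1e-2,
                                    random_state=0)
    ext.fit(modality_images, modality_images.labels.labels)
    return ext


@pytest.fixture(scope="session")
def trained_sae(modality_images):
    """Stacked autoencoder trained once for the whole suite."""
    ext = bf.SAEFeatureExtractor(max_epochs=2, minibatch=32,
                                 learning_rate=1e-3, random_state=0)
    ext.fit(modality_images)
    return ext


@pytest.fixture(scope="session")
def feature_data():
    """The standard planted-structure feature matrix (300 x 50)."""
    return bf.make_feature_dataset(300, 4, 5, 5, 40, 3.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
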