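import numpy as np
import pytest

from eegsaliency.classifier import TrainConfig, extract_features, train_classifier
from eegsaliency.eeg_io import prepare
from eegsaliency.synthetic import SynthConfig, generate_paired_dataset


@pytest.fixture(scope="session")
def desk_world():
    """Paired desk-scale dataset: 3 separable classes, 10 trials each, 63-px images."""
    cfg = SynthConfig(n_per_class=10, n_classes=3, seed=3, noise_sd=0.3,
                      image_size=63)
    records, images, maps, manifest = generate_paired_dataset(cfg)
    return prepare(records), images, maps, manifest


@pytest.fixture(scope="session")
def desk_classifier(desk_world):
    """A trained desk classifier with its features, shared across GAN tests."""
    records, _, _, _ = desk_world
    model, history = train_classifier(records, TrainConfig(iterations=150, seed=1))
    features = extract_features(model, records)
    return model, features, history
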