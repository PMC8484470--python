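import numpy as np
import pytest

from wbckit.synthetic import SyntheticSpec, make_crop, make_dataset
from wbckit.features import extract_features


@pytest.fixture(scope="session")
def crop_dataset():
    """100 synthetic crops, 20 per class, fixed seed."""
    return make_dataset(20, seed=42)


@pytest.fixture(scope="session")
def crop_features(crop_dataset):
    """Feature matrix and labels for the session dataset."""
    X = np.array([extract_features(c.image) for c in crop_dataset])
    y = np.array([c.label for c in crop_dataset])
    return X, y


@pytest.fixture(scope="session")
def lymphocyte_crop():
    return make_crop(SyntheticSpec("lymphocyte", seed=1))


@pytest.fixture(scope="session")
def neutrophil_crop():
    return make_crop(
        SyntheticSpec(
            "neutrophil",
            lobes=3,
            nucleus_radius=10,
            lobe_spacing=16,
            cytoplasm_radius=36,
            seed=2,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
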