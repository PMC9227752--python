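import numpy as np
import pytest

from beatselect.segmentation import BeatDataset
from beatselect.synthetic import SyntheticSpec, make_beats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_dataset():
    """Two well-separated Gaussian blobs (separation >> spread of the data)."""
    rng = np.random.default_rng(7)
    n = 100
    a = rng.normal(0.0, 0.5, size=(n, 2))
    b = rng.normal(10.0, 0.5, size=(n, 2))
    beats = np.vstack([a, b])
    labels = np.r_[np.ones(n, dtype=int), np.full(n, 2)]
    return BeatDataset(beats, labels)


@pytest.fixture(scope="session")
def imbalanced_beats():
    """Synthetic 8-class beats with the default heavy imbalance."""
    return make_beats(SyntheticSpec(n_beats=600, seed=11, noise_sd=0.05,
                                    ensure_all_classes=True, min_per_class=2))


@pytest.fixture(scope="session")
def planted_feature_dataset():
    """nf=8 feature-selection benchmark: class signal only in features {1, 2}."""
    spec = SyntheticSpec(
        n_beats=200,
        class_proportions=(0.5, 0.5, 0, 0, 0, 0, 0, 0),
        informative_features=(1, 2),
        informative_sep=2.5,
        n_features=8,
        seed=21,
    )
    return make_beats(spec)
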