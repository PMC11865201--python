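import numpy as np
import pytest

from ecaleaf.augment import expand_dataset, split_per_class
from ecaleaf.classifier import LeafDiseaseClassifier
from ecaleaf.synthdata import SyntheticLeafParams, generate_records


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_params():
    return SyntheticLeafParams(image_size=64, seed=11)


@pytest.fixture(scope="session")
def smoke_run(tiny_params):
    """Shared end-to-end run: 50/class synthetic at 64 px, 8:2 split,
    14-fold expansion of the training split, 3 training epochs."""
    records = generate_records(50, tiny_params)
    train_recs, test_recs = split_per_class(records, 0.8, seed=11)
    aug = expand_dataset(train_recs, seed=11)
    Xtr = np.stack([aug.load(r) for r in aug.records])
    ytr = np.array([r.label for r in aug.records])
    clf = LeafDiseaseClassifier(image_size=64, epochs=3, random_state=11)
    clf.fit(Xtr, ytr)
    return {"clf": clf, "train": train_recs, "test": test_recs, "aug": aug}
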