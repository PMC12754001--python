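import numpy as np
import pytest

from ctiqa import features, model, phantoms
from ctiqa.io_prep import GrayImage


@pytest.fixture(scope="session")
def phantom_dataset():
    """The 400-image synthetic phantom set used by the end-to-end suites."""
    manifest, samples = phantoms.make_dataset(400, seed=0)
    return manifest, samples


@pytest.fixture(scope="session")
def phantom_table(phantom_dataset):
    """Feature table (39 columns + score) for the 400-phantom set."""
    _, samples = phantom_dataset
    return features.table_from_images(
        [s.image for s in samples], [s.score for s in samples]
    )


@pytest.fixture(scope="session")
def tuned_pipeline(phantom_table):
    """Full training protocol on the phantom set: 80/20 split, SVR grid
    search, permutation-importance top-25 retrain.  Returns everything
    the acceptance checks need."""
    train_tab, test_tab = model.split_dataset(
        phantom_table, model.SplitSpec(train_fraction=0.8, seed=0)
    )
    cfg = model.ModelConfig(backend="svr", search="grid", seed=0)
    full = model.train(train_tab, cfg)
    imp = model.permutation_importance(full, test_tab, seed=0)
    selected = model.select_top_k(imp, k=25)
    final = model.train(train_tab, cfg, feature_subset=selected)
    return {
        "train": train_tab,
        "test": test_tab,
        "full_model": full,
        "importance": imp,
        "selected": selected,
        "model": final,
    }


@pytest.fixture
def constant_image():
    return GrayImage(pixels_float=np.full((32, 32), 0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_gray(rng, side=16):
    return GrayImage(pixels_float=rng.random((side, side)))
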