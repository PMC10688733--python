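import numpy as np
import pytest

from capsoct.synthetic_oct import CLASSES, SceneParams, render_scan


def make_arrays(n_per_class, seed, params=None):
    """In-memory balanced synthetic OCT arrays (X in [0,1], y indices)."""
    params = params or SceneParams()
    X, y = [], []
    for ci, cls in enumerate(CLASSES):
        for i in range(n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ci, i))
            )
            X.append(render_scan(cls, params, rng))
            y.append(ci)
    return np.asarray(X, dtype=np.float32), np.asarray(y)


@pytest.fixture(scope="session")
def small_train_set():
    return make_arrays(10, seed=11)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A tiny on-disk <split>/<class>/ dataset (6 train / 3 test / 3 val)."""
    from capsoct.synthetic_oct import generate_dataset

    root = tmp_path_factory.mktemp("octdata")
    generate_dataset(root, n_train=6, n_test=3, n_val=3, seed=5)
    return root
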