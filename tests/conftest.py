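import numpy as np
import pytest

from stenoskit.boxloss import Box


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box_pairs(rng, n, scale=10.0):
    """Random non-degenerate box pairs as (n, 4) center-format arrays."""
    centers = rng.uniform(-scale, scale, (2, n, 2))
    sizes = rng.uniform(0.1, scale / 2, (2, n, 2))
    a = np.concatenate([centers[0], sizes[0]], axis=1)
    b = np.concatenate([centers[1], sizes[1]], axis=1)
    return a, b


@pytest.fixture
def small_dataset(tmp_path_factory):
    """A tiny reusable synthetic dataset (8 train / 1 val / 1 test scenes)."""
    from stenoskit.synth import SceneParams, generate_dataset

    from stenoskit.harness import EXPERIMENT_SCENE

    out = tmp_path_factory.mktemp("synthdata")
    params = SceneParams(seed=7, **EXPERIMENT_SCENE)
    generate_dataset(params, 10, (0.8, 0.1, 0.1), out)
    return out
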