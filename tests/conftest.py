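import numpy as np
import pytest

import retivasc as rv


@pytest.fixture(scope="session")
def small_tree_params():
    """Half-scale scene: 512 px image, 30 px disc, same physical geometry."""
    return rv.TreeParams(seed=11, image_size=512, disc_radius=30.0,
                         px_per_micron=30.0 / 900.0, sine_amplitude=5.0,
                         sine_period=17.0)


@pytest.fixture(scope="session")
def small_scene(small_tree_params):
    tree = rv.simulate_tree(small_tree_params)
    return rv.render_scene(tree, seed=11)


@pytest.fixture(scope="session")
def default_scene():
    """One full-scale default scene (1024 px)."""
    tree = rv.simulate_tree(rv.TreeParams(seed=5))
    return rv.render_scene(tree, seed=5)


@pytest.fixture(scope="session")
def default_cohort():
    return rv.simulate_cohort(rv.CohortParams(seed=42))


@pytest.fixture(scope="session")
def per_child(default_cohort):
    return rv.average_metrics(default_cohort)


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
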