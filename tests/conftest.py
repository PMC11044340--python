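import numpy as np
import pytest

import chromadapt as ca


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240425)


@pytest.fixture(scope="session")
def tree27():
    return ca.simulate_tree(27, seed=1)


@pytest.fixture(scope="session")
def uniform_scene():
    spec = ca.SceneSpec(pattern="uniform", coverage=0.0, noise_sd=0.0, seed=3)
    return ca.render_scene(spec)


@pytest.fixture(scope="session")
def striped_scene():
    spec = ca.SceneSpec(
        pattern="striped", pattern_lab=(48.0, 18.0, 30.0), coverage=0.5, noise_sd=0.0, seed=4
    )
    return ca.render_scene(spec)


@pytest.fixture(scope="session")
def two_cluster_pool():
    """Planted two-Gaussian colour pool: separation 10x the within-cluster sd."""
    r = np.random.default_rng(11)
    mu1 = np.array([55.0, -38.0, 32.0])
    mu2 = np.array([48.0, 18.0, 30.0])
    sd = np.linalg.norm(mu1 - mu2) / 10.0
    pool = np.vstack(
        [mu1 + sd * r.standard_normal((2000, 3)), mu2 + sd * r.standard_normal((2000, 3))]
    )
    return pool, mu1, mu2, sd


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    ds = ca.simulate_dataset(seed=11)
    out = tmp_path_factory.mktemp("bundle")
    ds.write(out)
    return ds, out
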