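import numpy as np
import pytest

import toscca


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pair(rng):
    """Unstructured 20-sample pair (p=10, q=8) for oracle comparisons."""
    x1 = rng.standard_normal((20, 10))
    x2 = rng.standard_normal((20, 8))
    return toscca.standardize(x1, x2)


@pytest.fixture
def planted():
    """Small two-component planted dataset with a strong signal.

    Returns (pair, truth, design): n=60, p=80, q=50, supports of sizes
    (15, 10) and (12, 8), latent scales (3, 2) against unit noise.
    """
    design = toscca.SimulationDesign(
        n=60, p=80, q=50, k_true=2,
        support_sizes_1=(15, 10), support_sizes_2=(12, 8),
        latent_sd=(3.0, 2.0), noise_sd=1.0, seed=7,
    )
    x1, x2, truth = toscca.generate(design)
    return toscca.standardize(x1, x2), truth, design


@pytest.fixture
def null_pair():
    """Independent pure-noise pair (no shared signal)."""
    design = toscca.SimulationDesign(
        n=40, p=30, q=20, k_true=0,
        support_sizes_1=(), support_sizes_2=(), latent_sd=(), seed=21,
    )
    x1, x2, _ = toscca.generate(design)
    return toscca.standardize(x1, x2)
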