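import numpy as np
import pytest

import sparsekernels as sk


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def scaled_markers(rng):
    """A small centered/scaled dosage matrix (20 lines x 15 markers)."""
    X = rng.binomial(2, 0.3, size=(20, 15)).astype(float)
    return sk.center_scale(X)


@pytest.fixture
def small_trial():
    """Single-environment simulated trial with known truth (h2 = 0.5)."""
    cfg = sk.SimConfig(n_lines=120, p_markers=150, h2=0.5, n_env=1,
                       env_effect_sd=0.0, seed=42)
    X, pheno, truth = sk.simulate_dataset(cfg)
    return X, pheno, truth
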