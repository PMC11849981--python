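import numpy as np
import pytest

import chromafactor as cf


@pytest.fixture(scope="session")
def planted_small():
    """A small planted ensemble reused across modules: 16 bins, 3 templates
    (boundary @8, stripe @4, checkerboard period 2), 120 cells, light noise."""
    config = cf.SyntheticConfig(b=16, k_true=3, n=120, noise_sd=0.02,
                                dropout_frac=0.0, seed=42)
    return cf.generate_dataset(config)


@pytest.fixture(scope="session")
def planted_small_fit(planted_small):
    """Deterministic k=3 fit of the small planted ensemble."""
    model = cf.ChromaFactorModel(planted_small.tensor)
    return model.fit(k=3, seed=0)


def two_block_matrix(b=8, split=4, within=0.1, cross=0.9):
    """Two self-interacting blocks separated at ``split`` (distance scale)."""
    side = (np.arange(b) >= split).astype(int)
    M = np.where(side[:, None] == side[None, :], within, cross).astype(float)
    np.fill_diagonal(M, 0.0)
    return M
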