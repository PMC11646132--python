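import numpy as np
import pytest

from m6afuse.config import ModelConfig


@pytest.fixture
def tiny_config():
    """A desk-size configuration (L<=16, C<=8) in float64 for oracle checks."""
    return ModelConfig(
        L_max=12, embed_dim=3, out_channel=8, reduction_ratio=4,
        n_dr_blocks=2, batch_size=4, epochs=2, dtype="float64", seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_codes(rng, n, length):
    """Valid encoded rows: a padded prefix of zeros then nonzero codes."""
    codes = np.zeros((n, length), dtype=np.int64)
    for i in range(n):
        body = int(rng.integers(1, length + 1))
        codes[i, length - body:] = rng.integers(1, 5, size=body)
    return codes
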