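import numpy as np
import pytest

from lpbn import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def and_target_dataset():
    """Realizable target y = z0 AND z2 on a random 6-bit substrate."""
    gen = np.random.default_rng(0)
    Z = gen.integers(0, 2, size=(600, 6)).astype(np.uint8)
    y = (Z[:, 0] & Z[:, 2]).astype(np.int64)
    return sd.Dataset(
        Z,
        y,
        np.arange(400),
        np.arange(400, 500),
        np.arange(500, 600),
        meta={"binary": True},
    )


@pytest.fixture
def parity_dataset():
    """y = z0 XOR z1 on a random 4-bit substrate."""
    gen = np.random.default_rng(0)
    Z = gen.integers(0, 2, size=(600, 4)).astype(np.uint8)
    y = (Z[:, 0] ^ Z[:, 1]).astype(np.int64)
    return sd.Dataset(
        Z,
        y,
        np.arange(400),
        np.arange(400, 500),
        np.arange(500, 600),
        meta={"binary": True},
    )


@pytest.fixture(scope="session")
def cellcycle():
    return sd.cellcycle_fixture()
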