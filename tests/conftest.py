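import numpy as np
import pytest

from zebratrain import CellPreset, generate_cell


@pytest.fixture(scope="session")
def base_preset():
    return CellPreset(name="base", ss_rate_mean=80.0, ss_rate_sd=10.0,
                      ss_shape=4.0, cs_rate=1.0, cf_pause_ms=10.0)


@pytest.fixture(scope="session")
def base_cell(base_preset):
    """One 120-s synthetic cell shared by read-only tests."""
    return generate_cell(base_preset, 120.0, seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def poisson_train(rng, rate_hz, n_isi):
    """Homogeneous Poisson spike train with n_isi intervals."""
    return np.cumsum(rng.exponential(1.0 / rate_hz, n_isi + 1))
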