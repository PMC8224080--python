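import io

import numpy as np
import pytest

from causalinfo import TimeSeriesDataset, chain_spec, simulate_linear


@pytest.fixture(scope="session")
def chain_data_small():
    """Chain-model dataset at the benchmark parameters, n = 10^4."""
    return simulate_linear(chain_spec(), 10_000, seed=42)


@pytest.fixture(scope="session")
def chain_data_desk():
    """Chain-model dataset at desk scale, n = 2x10^4."""
    return simulate_linear(chain_spec(), 20_000, seed=7)


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(0)
    return TimeSeriesDataset(
        {
            "X": rng.normal(size=(60, 1)),
            "Y": rng.normal(size=(60, 2)),
            "Z": rng.normal(size=(60, 1)),
        }
    )


@pytest.fixture
def csv_buffer():
    def make(text: str) -> io.StringIO:
        return io.StringIO(text)

    return make
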