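import datetime as dt

import numpy as np
import pytest

from egretwatch import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sprite_pool():
    return synthetic.generate_sprites(seed=1, n_poses=2)


@pytest.fixture(scope="session")
def background():
    return synthetic.generate_background(400, 300, seed=0)


@pytest.fixture(scope="session")
def two_day_stream():
    """Noise-free two-day detection stream plus its ground-truth ledger."""
    config = synthetic.SimulationConfig(
        days=[dt.date(2019, 9, 23), dt.date(2019, 9, 24)], rng_seed=7
    )
    records, ledger = synthetic.simulate_detections(config)
    return config, records, ledger
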