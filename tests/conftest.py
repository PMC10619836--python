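import random

import pandas as pd
import pytest
from hypothesis import settings

from allosim import SimConfig, run
from allosim.analysis import fitness_table

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

#: Reference run's per-bin population counts (lifetime
#: offspring -> number of agents); used as a printed-table fixture.
REFERENCE_BINS = {
    0: 13440, 1: 6413, 2: 1702, 3: 481, 4: 269, 5: 182, 6: 126,
    7: 122, 8: 92, 9: 65, 10: 54, 11: 42, 12: 37,
}


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture(scope="session")
def small_run():
    """A 5-year default-parameter run with event logging, shared across tests."""
    return run(SimConfig(years=5, log_events=True), seed=42)


@pytest.fixture(scope="session")
def small_records(small_run):
    return small_run.records_frame()


@pytest.fixture(scope="session")
def small_table(small_records):
    return fitness_table(small_records)


@pytest.fixture(scope="session")
def reference_offspring_bins():
    """Offspring counts expanded from the printed population bins."""
    counts = []
    for k, n in REFERENCE_BINS.items():
        counts.extend([k] * n)
    return pd.Series(counts, name="offspring")
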