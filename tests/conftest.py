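import numpy as np
import pytest

from pregbs.io import SequenceRecord
from pregbs.motif import GR_MOTIF_PATTERN, compile_motif
from pregbs.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def gr_motif():
    return compile_motif(GR_MOTIF_PATTERN)


@pytest.fixture(scope="session")
def small_dataset():
    """A 60 kb two-lineage simulation shared by read-only pipeline tests."""
    config = SimulationConfig(length=60_000, n_cpg_sites=40, n_tpg_sites=120)
    return simulate_dataset(config, seed=7)


@pytest.fixture
def random_sequence():
    def make(length: int, seed: int, alphabet: str = "ACGT") -> SequenceRecord:
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(alphabet), size=length))
        return SequenceRecord(f"rand{seed}", seq)

    return make
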