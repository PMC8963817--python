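import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rpistack.seqio import SequenceRecord
from rpistack.synthetic_data import SimulationConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rna_record():
    return SequenceRecord("r1", "ACGUACGUACGUACGU", "rna")


@pytest.fixture
def protein_record():
    return SequenceRecord("p1", "MKVLAGDERKCWHNQ", "protein")


@pytest.fixture(scope="session")
def small_dataset():
    """Compact simulated dataset with planted signal for pipeline tests."""
    cfg = SimulationConfig(n_rnas=10, n_proteins=40, n_pairs=64,
                           rna_length_range=(50, 300),
                           protein_length_range=(50, 150), seed=7)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
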