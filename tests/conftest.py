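import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitar.fixtures import SynthConfig, gen_dataset
from mitar.seqio import MiRNASeq, UTRSeq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def let7a() -> MiRNASeq:
    return MiRNASeq("hsa-let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


def utr_with(motif: str, pad: int = 20) -> UTRSeq:
    """A UTR carrying exactly one pairing-inert padded motif."""
    return UTRSeq("u1", "GG" * (pad // 2) + motif + "GG" * (pad // 2))


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by feature/CV unit tests."""
    return gen_dataset(SynthConfig(n_pos=60, n_neg=60, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
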