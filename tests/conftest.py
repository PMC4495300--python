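import numpy as np
import pytest
from hypothesis import settings

from slimq.seqdata import AMINO_ACIDS, ProteinRecord

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_record(rid, sequence, disordered=True):
    """A record with uniform disorder scores (all-disordered by default)."""
    score = 0.8 if disordered else 0.05
    return ProteinRecord(rid, sequence, (score,) * len(sequence))
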