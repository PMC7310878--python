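import numpy as np
import pytest

from pirnasig import ConsensusRecord, RefCategory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_record(rng, rec_id: str, length: int, category=RefCategory.TE) -> ConsensusRecord:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return ConsensusRecord(rec_id, seq, category)


def mutate(rng, seq: str, n_subs: int) -> str:
    chars = list(seq)
    sites = rng.choice(len(chars), size=n_subs, replace=False)
    for pos in sites:
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


@pytest.fixture
def te_pair(rng):
    """A 1000-nt TE consensus and a copy with 50 substitutions (95% identity)."""
    a = random_record(rng, "TEa", 1000)
    b = ConsensusRecord("TEb", mutate(rng, a.seq, 50), RefCategory.TE)
    return a, b
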