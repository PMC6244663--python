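import numpy as np
import pytest

import codonbias as cb


@pytest.fixture(scope="session")
def code():
    return cb.standard_code()


@pytest.fixture(scope="session")
def human_table():
    return cb.human_like_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_cds(rng, n_codons, code, id="rnd", with_stop=True):
    """Draw a random in-frame CDS with no internal stops."""
    coding = sorted(c for c, aa in code.mapping.items() if aa != "*")
    idx = rng.integers(0, len(coding), size=n_codons - (1 if with_stop else 0))
    codons = [coding[i] for i in idx]
    if with_stop:
        codons.append("TAA")
    return cb.CodingSequence(id=id, sequence="".join(codons))
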