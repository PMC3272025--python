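import numpy as np
import pytest

from sinekit import synthetic_data as sd
from sinekit.seqcore import NucSequence

BASES = np.array(["A", "C", "G", "T"])


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20120203)


@pytest.fixture(scope="session")
def reference_rnas():
    """A tRNA-like and a 5S-like reference for head classification."""
    rng = np.random.default_rng(55)
    five_s = "".join(np.random.default_rng(99).choice(BASES, size=120))
    return [
        NucSequence("trnaGlu_ref", sd.DEFAULT_HEAD, "tRNA-Glu reference"),
        NucSequence("ref_5S", five_s, "5S rRNA reference"),
    ]


@pytest.fixture(scope="session")
def family_consensus():
    return sd.make_consensus(sd.FamilySpec(), seed=20120203)
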