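import numpy as np
import pytest

from gplmdca.alignment import EncodedMSA, msa_from_strings


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_msa():
    """A tiny hand-written alignment with gaps."""
    return msa_from_strings([
        "ACD-EF--KL",
        "ACDWEF--KL",
        "A--WEFGHKL",
        "MCDWEF--KL",
        "ACD-EFGHKL",
        "WWDWEFGHKL",
    ])


def random_msa(rng, B, N, q=21, weights=None):
    data = rng.integers(0, q, size=(B, N))
    w = weights if weights is not None else np.ones(B)
    return EncodedMSA(data=data, weights=w, q=q)
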