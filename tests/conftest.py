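import numpy as np
import pytest

from hybridswarm.architecture import (
    Architecture,
    GenomeMap,
    IncompatibilityPair,
    LocusRef,
    unlinked_coevolving_architecture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def codominant_pair():
    """One coevolving incompatibility pair, s1 = s2 = 0.1, h = 0.5."""
    return IncompatibilityPair(
        id="pair0",
        kind="coevolving",
        locusA=LocusRef(0, 0.5),
        locusB=LocusRef(1, 0.5),
        s1=0.1,
        s2=0.1,
        hA=0.5,
        hB=0.5,
    )


@pytest.fixture
def two_pair_architecture():
    """The two-pair unlinked codominant workhorse architecture."""
    return unlinked_coevolving_architecture(2, s=0.1, h=0.5)


@pytest.fixture
def underdominant_pair():
    return IncompatibilityPair(
        id="inv0",
        kind="underdominant",
        locusA=LocusRef(0, 0.5),
        locusB=None,
        s1=0.05,
    )
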