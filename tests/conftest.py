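import numpy as np
import pytest

from bulgescan import (
    BCBP_SITE_SYNTHETIC,
    MIR398A,
    MIR398BC,
    NucleotideSequence,
    default_model,
    duplex_mfe,
)


@pytest.fixture(scope="session")
def model():
    m = default_model()
    # warm the numba kernel once so per-call timings reflect the DP itself
    warm = NucleotideSequence(id="warm", residues="ACGUACGUACGUACGUACGU")
    duplex_mfe(warm, warm, m)
    return m


@pytest.fixture(scope="session")
def mir398a():
    return MIR398A


@pytest.fixture(scope="session")
def mir398bc():
    return MIR398BC


@pytest.fixture(scope="session")
def bcbp_site():
    return BCBP_SITE_SYNTHETIC


@pytest.fixture(scope="session")
def bcbp_alignment(model, mir398a, bcbp_site):
    """The packaged miR398a vs synthetic-BCBP-site optimal alignment."""
    aln = duplex_mfe(mir398a, bcbp_site, model)
    assert aln is not None
    return aln


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)
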