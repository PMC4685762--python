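import numpy as np
import pytest

from ratewalk import LatticeSpec, datasets


@pytest.fixture(scope="session")
def spec():
    """The standard 9-rating, 11-states-per-rating lattice."""
    return LatticeSpec()


@pytest.fixture(scope="session")
def observed_tables():
    """Packaged observed relative-frequency tables (self-first, other-first)."""
    return datasets.load_observed_tables()


@pytest.fixture(scope="session")
def observed_counts(observed_tables):
    """Counts reconstructed from the printed percentages (fractional)."""
    sf, of = observed_tables
    return sf.to_counts(), of.to_counts()


@pytest.fixture(scope="session")
def quantum_sse_estimate():
    return datasets.REFERENCE_ESTIMATES[("sse", "quantum")]


@pytest.fixture(scope="session")
def markov_sse_estimate():
    return datasets.REFERENCE_ESTIMATES[("sse", "markov")]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160113)
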