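import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_scheme():
    from lvsynapse import make_fixture_scheme
    return make_fixture_scheme("fast_ampa_like")


@pytest.fixture(scope="session")
def fast_oracle(fast_scheme):
    from lvsynapse import KineticOracle
    return KineticOracle(fast_scheme)


def random_small_model(rng, order, cross_terms, L=(2, 2), dt=1e-3,
                       window=0.05, decays=(0.4, 0.05)):
    """A random Volterra model small enough for brute-force evaluation."""
    from lvsynapse import VolterraModel, build_basis, enumerate_terms
    bases = [build_basis(p, n, dt, window) for p, n in zip(decays, L)]
    terms = enumerate_terms(order, L, cross_terms)
    coefs = rng.normal(scale=0.5, size=len(terms))
    return VolterraModel(order=order, bases=bases, cross_terms=cross_terms,
                         term_index=terms, c0=rng.normal(scale=0.1),
                         coefficients=coefs)
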