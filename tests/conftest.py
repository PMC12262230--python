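"""Shared fixtures: one small synthetic session analyzed end to end.

The default session (5 units per subtype, 99 trials) is generated once
per test run and shared read-only across modules; tests that need other
generator settings build their own bundles.
"""
import numpy as np
import pytest

import scvigor
from scvigor import session as sess
from scvigor.synth import GeneratorParams


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams(seed=1234)


@pytest.fixture(scope="session")
def bundle(default_params):
    return scvigor.generate_session(default_params)


@pytest.fixture(scope="session")
def saccades(bundle):
    return sess.analyze_saccades(bundle)


@pytest.fixture(scope="session")
def classes(bundle, saccades):
    return sess.classify(bundle, saccades)


@pytest.fixture(scope="session")
def rasters(bundle, saccades):
    return sess.unit_rasters(bundle, saccades)


def make_session(seed, n_units=5, **overrides):
    """Convenience constructor for per-test generator variants."""
    params = GeneratorParams(seed=seed, n_units_per_subtype=n_units, **overrides)
    return scvigor.generate_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
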