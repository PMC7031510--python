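import numpy as np
import pytest

from hvcx import hh
from hvcx.fitting import simulate_canonical_pair


@pytest.fixture(scope="session")
def ref_params():
    return hh.reference_parameters()


@pytest.fixture(scope="session")
def ref_pair(ref_params):
    """Reference-model responses to the canonical +100 / -140 pA pulses."""
    return simulate_canonical_pair(ref_params, depol_post_ms=200.0)


@pytest.fixture(scope="session")
def ref_depol(ref_pair):
    return ref_pair[0]


@pytest.fixture(scope="session")
def ref_hyperpol(ref_pair):
    return ref_pair[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def noisy(trace, sigma, seed):
    """Copy of a trace with seeded additive Gaussian voltage noise."""
    r = np.random.default_rng(seed)
    return hh.Trace(
        t=trace.t,
        v=trace.v + r.normal(0.0, sigma, len(trace.v)),
        i=trace.i,
        meta={**trace.meta, "noise_sigma_mV": sigma},
    )
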