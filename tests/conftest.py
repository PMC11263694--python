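import numpy as np
import pytest

from neurostates import segmentation as seg
from neurostates import synth


@pytest.fixture(scope="session")
def example_params():
    return seg.example_params()


@pytest.fixture(scope="session")
def long_symbol_stream(example_params):
    """1e5 symbols drawn from the example-session parameters."""
    states = synth.simulate_state_sequence(example_params, 100_000, seed=1)
    symbols = synth.simulate_symbols(states, example_params.B, seed=1)
    return states, symbols


def simulate_var(coefs, cov, n, seed, burn=300):
    """Direct VAR simulation used as an independent oracle for the granger
    module (deliberately not via neurostates.synth)."""
    coefs = np.asarray(coefs, float)
    p, n_ch, _ = coefs.shape
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    eps = rng.standard_normal((n + burn, n_ch)) @ chol.T
    x = np.zeros((n + burn, n_ch))
    for t in range(p, n + burn):
        x[t] = eps[t] + sum(coefs[k] @ x[t - k - 1] for k in range(p))
    return x[burn:]


@pytest.fixture(scope="session")
def var_simulator():
    return simulate_var
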