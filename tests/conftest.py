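import numpy as np
import pytest

import endokin as ek


def random_rates(rng, lo=1e-4, hi=1e-2, short_circuits=True):
    """Log-uniform random coefficient set, optionally without short circuits."""
    k = np.exp(rng.uniform(np.log(lo), np.log(hi), size=6))
    if not short_circuits:
        k[4:] = 0.0
    return ek.RateCoefficientSet.from_array(k)


@pytest.fixture(scope="session")
def k_true():
    return ek.DEFAULT_K_TRUE


@pytest.fixture(scope="session")
def ongrid_k0(k_true):
    # K_true sits exactly on the 6-value grid (exponent +0.4 decades from K0)
    return ek.RateCoefficientSet.from_array(k_true.as_array() * 10**-0.4)


@pytest.fixture(scope="session")
def noiseless_obs():
    return ek.gen_timecourse(ek.GeneratorSpec(seed=101, noise_sd=0.0))[0]


@pytest.fixture(scope="session")
def noisy_obs():
    return ek.gen_timecourse(ek.GeneratorSpec(seed=202))[0]


@pytest.fixture(scope="session")
def noisy_fit(ongrid_k0, noisy_obs):
    return ek.fit_pipeline(ongrid_k0, noisy_obs, n_values=6)
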