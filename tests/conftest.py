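import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_complex_pair(rng, n=None, kind=None):
    """A random complex pair from a mixed family of distributions.

    Covers proper/improper Gaussian, bursty, heavy-tailed and
    constant-modulus-carrier signals so identity tests see pathological
    inputs, not just Gaussian ones.
    """
    n = n or int(rng.integers(16, 2000))
    kind = kind or rng.choice(["gaussian", "coherent", "bursty", "improper", "heavy", "phase"])
    w = lambda: (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
    if kind == "gaussian":
        return w(), w()
    if kind == "coherent":
        x = w()
        g = rng.uniform(0, 0.95)
        return x, g * np.exp(1j * rng.uniform(0, np.pi)) * x + np.sqrt(1 - g**2) * w()
    if kind == "bursty":
        b = (rng.random(n) < 0.1).astype(float)
        x = (1 + 3 * b) * w()
        y = (1 + 3 * b) * w() + 0.3 * x
        return x, y
    if kind == "improper":
        x = rng.standard_normal(n) + 0.2j * rng.standard_normal(n)
        y = 0.5 * np.conj(x) + w()
        return x, y
    if kind == "heavy":
        return w() * rng.standard_t(3, n), w() * rng.standard_t(3, n)
    # constant-modulus carriers with random phases plus a small perturbation
    x = np.exp(1j * rng.uniform(0, 2 * np.pi, n))
    y = np.exp(1j * rng.uniform(0, 2 * np.pi, n)) + 0.1 * x
    return x, y
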