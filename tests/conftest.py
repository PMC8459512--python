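"""Shared fixtures and the probability-space brute-force oracle."""
import numpy as np
import pytest
from scipy.stats import poisson


def brute_force_loglik(x, y, m, c, gamma, gamma_final, epsilon, phi, uniform=False):
    """Independent oracle: enumerate every latent cell count n in 0..c and
    sum the Poisson pmfs in probability space."""
    n = np.arange(int(c) + 1)
    if uniform:
        prior = np.full(n.size, 1.0 / (c + 1))
    else:
        prior = poisson.pmf(n, c * m)
    px = poisson.pmf(x, gamma * n) if x is not None else 1.0
    py = poisson.pmf(y, gamma_final * n * (1.0 - epsilon * phi))
    total = float(np.sum(prior * px * py))
    return np.log(total) if total > 0 else -np.inf


@pytest.fixture
def oracle():
    return brute_force_loglik


def random_instance(rng):
    """One guide-sample instance in the regime the bundled sum targets:
    c = 200 infected cells, prior mean 100-190, 0.3-1 reads per cell."""
    c = 200
    m = rng.uniform(0.5, 0.95)
    gamma = rng.uniform(0.3, 1.0)
    gamma_final = rng.uniform(0.3, 1.0)
    epsilon = rng.uniform(0.5, 1.0)
    phi = rng.uniform(-0.5, 0.9)
    n = rng.poisson(c * m)
    x = rng.poisson(gamma * n)
    y = rng.poisson(gamma_final * n * (1 - epsilon * phi))
    return dict(x=x, y=y, m=m, c=c, gamma=gamma, gamma_final=gamma_final,
                epsilon=epsilon, phi=phi)


@pytest.fixture(scope="session")
def tiny_screen():
    """A small simulated screen with known truth, reused across tests.

    81 genes (63 nonessential, 6 at phi=0.5, 12 at phi=0.99), 4 guides
    per gene, 3 replicates; the nonessential genes are the designated
    negative controls.
    """
    from crisphi.simulate import build_benchmark

    ds, lib, truth, neg = build_benchmark(
        "absolute", level_values=(0.5, 0.99), seed=7, scale=0.02
    )
    return ds, lib, truth, neg
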