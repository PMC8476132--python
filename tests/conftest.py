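import numpy as np
import pytest

from hybridscan import HaplotypeSample, SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def neutral_params():
    """Tiny neutral-ish parameter set for fast forward runs."""
    return SimParams(
        Np=60,
        N=120,
        n_burnin=120,
        mu=2e-7,
        r=2e-8,
        rescale=1,
        L=400_000,
        pos_A=140_000,
        pos_B=260_000,
        eps=0.0,
        m=0.01,
        seed=11,
        sample_size=15,
        sample_generations=(5, 20),
    )


def random_sample(rng, n_sites=120, n_hap=20, L=60_000, generation=None) -> HaplotypeSample:
    """A random polarized sample with every site polymorphic."""
    positions = np.sort(rng.choice(L, size=n_sites, replace=False))
    G = np.zeros((n_sites, n_hap), dtype=np.uint8)
    for s in range(n_sites):
        c = rng.integers(1, n_hap)
        G[s, rng.choice(n_hap, size=c, replace=False)] = 1
    return HaplotypeSample(positions=positions, genotypes=G, sequence_length=L,
                           generation=generation)


@pytest.fixture
def small_sample(rng):
    return random_sample(rng)
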