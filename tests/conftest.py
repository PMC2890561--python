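import numpy as np
import pytest

from condld import GenotypeCountTable, PopulationParams, d_bounds, joint_probs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_params(rng, p_range=(0.1, 0.9), q_range=(0.1, 0.9), margin=0.1):
    """A random feasible (p, q, D) kept away from the bound edges."""
    p = rng.uniform(*p_range)
    q = rng.uniform(*q_range)
    lo, hi = d_bounds(p, q)
    D = rng.uniform(lo * (1 - margin), hi * (1 - margin))
    return PopulationParams(p, q, D)


def expectation_table(params: PopulationParams, n: float) -> GenotypeCountTable:
    """Noise-free table: n times the joint genotype probabilities."""
    return GenotypeCountTable(n * joint_probs(params).P)


def random_table(rng, params: PopulationParams, n: int) -> GenotypeCountTable:
    probs = joint_probs(params).P.ravel()
    return GenotypeCountTable(rng.multinomial(n, probs / probs.sum()).reshape(3, 3))
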