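import numpy as np
import pytest

from stagessm import (
    DemographicRates,
    ObservationRate,
    build_lefkovitch,
    default_scenario,
    generate_dataset,
)

#: posterior-median rates of the reference analysis; the canonical
#: worked example throughout the suite
MEDIAN_RATES = DemographicRates(
    j1=0.45, j2=0.20, p1=0.60, s=0.42, p2=0.42, a=0.72, f=0.82)


@pytest.fixture(scope="session")
def median_rates():
    return MEDIAN_RATES


@pytest.fixture(scope="session")
def median_matrix():
    return build_lefkovitch(MEDIAN_RATES)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic 13-census dataset under the canonical scenario."""
    sc = default_scenario()
    data, truth = generate_dataset(sc)
    return sc, data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_valid_rates(rng, n):
    """Draw n rate vectors uniformly over the joint support."""
    out = []
    for _ in range(n):
        p_j2 = rng.uniform(0.05, 0.95)
        g1 = rng.uniform(0.05, 0.95)
        p_s = rng.uniform(0.05, 0.95)
        g2 = rng.uniform(0.05, 0.95)
        out.append(DemographicRates(
            j1=rng.uniform(0.05, 0.95),
            j2=p_j2 * (1 - g1), p1=p_j2 * g1,
            s=p_s * (1 - g2), p2=p_s * g2,
            a=rng.uniform(0.05, 0.95), f=rng.uniform(0.05, 1.95)))
    return out
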