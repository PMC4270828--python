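import numpy as np
import pytest

from epihier import (
    DiscreteDistribution,
    HierarchyModel,
    hwe_distribution,
    parity_dataset,
    reference_model,
)


@pytest.fixture(scope="session")
def genotype_dist() -> DiscreteDistribution:
    """HWE genotype distribution at equal allele frequencies."""
    return hwe_distribution(0.5)


@pytest.fixture(scope="session")
def all_add_model() -> HierarchyModel:
    return reference_model(1)


@pytest.fixture(scope="session")
def parity() :
    return parity_dataset()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
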