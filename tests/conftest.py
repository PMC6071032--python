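import numpy as np
import pytest

from picafuse.synthetic import CohortSpec, generate_coupled_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A fast desk-scale tail-driven cohort specification."""
    return CohortSpec(n_subjects=300, n_snps=600, n_voxels=800,
                      n_components_snp=4, n_components_gmc=4,
                      coupled_pair_rho=0.3, n_tail_subjects=12,
                      n_sites=5, n_related_pairs=1, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_coupled_cohort(small_spec)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
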