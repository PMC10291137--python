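import numpy as np
import pytest

from pdxplore.synthetic import (
    CohortSpec,
    simulate_expression_cohort,
    simulate_fusion_calls,
    simulate_variant_cohort,
)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_patients=2,
        n_genes=400,
        n_me_genes=40,
        n_variants_shared=10,
        n_variants_relapse_gained=5,
        n_variants_pdx_private=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def variant_cohort(small_spec):
    return simulate_variant_cohort(small_spec)


@pytest.fixture(scope="session")
def fusion_cohort(small_spec):
    return simulate_fusion_calls(small_spec)


@pytest.fixture(scope="session")
def expression_cohort():
    spec = CohortSpec(n_patients=4, n_genes=800, n_me_genes=80, seed=7)
    return simulate_expression_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
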