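import numpy as np
import pytest

from tadard.synthetic_data import (
    CovariateModel,
    generate_family_variants,
    generate_gene_table,
    separable_covariate_model,
)


@pytest.fixture(scope="session")
def gene_table():
    """300 genes, 6% risk, with mutation rates, family BFs and case counts."""
    return generate_gene_table(300, 0.06, seed=101)


@pytest.fixture(scope="session")
def covariate_model():
    return CovariateModel(seed=101)


@pytest.fixture(scope="session")
def separable_model():
    return separable_covariate_model(seed=101)


@pytest.fixture(scope="session")
def family_cohort(covariate_model, gene_table):
    """Labeled family-based training cohort at a realistic ~30:1 imbalance."""
    return generate_family_variants(100, 3000, covariate_model, gene_table, seed=7)


@pytest.fixture(scope="session")
def family_test_cohort(covariate_model, gene_table):
    """Disjoint labeled cohort for held-out evaluation."""
    return generate_family_variants(300, 9000, covariate_model, gene_table, seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
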