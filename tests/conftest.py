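import numpy as np
import pytest

from rvinteract.collapse import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n_samples=40, n_genes=3, n_snps=4, maf=0.2, binary=True):
    """Small random dataset helper shared across test modules."""
    n_variants = n_genes * n_snps
    genotypes = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(np.int8)
    genes = [f"G{k}" for k in range(n_genes)]
    gene_of = np.repeat(genes, n_snps)
    phenotype = rng.integers(0, 2, n_samples).astype(float) if binary else rng.normal(size=n_samples)
    # guarantee both classes
    if binary:
        phenotype[0], phenotype[1] = 0.0, 1.0
    return GenotypeDataset(
        genotypes=genotypes,
        variant_ids=[f"v{j}" for j in range(n_variants)],
        gene_of=gene_of,
        phenotype=phenotype,
        sample_ids=[f"s{i}" for i in range(n_samples)],
    )


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)
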