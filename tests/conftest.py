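import numpy as np
import pytest

from genimg import GenotypeDataset, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> GenotypeDataset:
    """A 600 x 400 cohort with a handful of strong causal SNPs."""
    cfg = SimConfig(
        n_samples=600,
        n_snps=400,
        n_causal=4,
        heritability=0.8,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_dataset() -> GenotypeDataset:
    """A hand-sized 6 x 4 dataset with fixed genotypes and labels."""
    return GenotypeDataset(
        genotypes=np.array(
            [
                [0, 1, 2, 0],
                [1, 1, 0, 0],
                [2, 0, 1, 1],
                [0, 2, 2, 0],
                [1, 0, 0, 2],
                [2, 1, 1, 1],
            ]
        ),
        snp_ids=np.array([f"rs{j}" for j in range(1, 5)], dtype=object),
        positions=np.array([100, 200, 350, 500]),
        sample_ids=np.array([f"s{i}" for i in range(1, 7)], dtype=object),
        phenotype=np.array([0, 0, 0, 1, 1, 1]),
    )
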