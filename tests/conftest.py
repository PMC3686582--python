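import numpy as np
import pytest

from snpselect import GenotypeMatrix, SimulationConfig, simulate_dataset


def make_matrix(values, labels, snp_prefix="X"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return GenotypeMatrix(
        values,
        [f"{snp_prefix}{j + 1}" for j in range(d)],
        [f"s{i + 1}" for i in range(n)],
        np.asarray(labels, dtype=int),
    )


@pytest.fixture
def causal_data():
    """300 subjects x 40 SNPs with three strong main-effect SNPs (X1..X3)."""
    cfg = SimulationConfig(
        n_cases=150,
        n_controls=150,
        n_snps=40,
        maf_range=(0.2, 0.5),
        causal_snps=[(0, 3.0), (1, 3.0), (2, 3.0)],
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def null_data():
    """200 subjects x 30 SNPs with no genotype-phenotype association."""
    cfg = SimulationConfig(n_cases=100, n_controls=100, n_snps=30, maf_range=(0.2, 0.5), seed=7)
    return simulate_dataset(cfg)
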