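import numpy as np
import pytest

from imprintvar.regressors import PhasedGenotypeMatrix, SNPInfo, compute_regressors
from imprintvar.simulate import make_snp_panel, simulate_genotypes


@pytest.fixture
def tiny_matrix():
    """3 individuals x 2 SNPs with certain phase, no missing calls."""
    snps = [SNPInfo("s1", "1", 100), SNPInfo("s2", "1", 200)]
    P1 = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
    P2 = np.array([[1.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
    return PhasedGenotypeMatrix(["a", "b", "c"], snps, P1, P2)


@pytest.fixture(scope="session")
def hwe_cohort():
    """A larger HWE cohort with known frequencies for moment checks."""
    snps = make_snp_panel(20, n_chromosomes=4, rng=np.random.default_rng(11))
    return simulate_genotypes(12_000, snps, seed=42).with_frequencies()


@pytest.fixture(scope="session")
def small_fit_data():
    """A small cohort plus regressors for quick sampler runs."""
    snps = make_snp_panel(60, n_chromosomes=6, rng=np.random.default_rng(3))
    G = simulate_genotypes(250, snps, seed=7).with_frequencies()
    return G, compute_regressors(G)
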