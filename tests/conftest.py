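import numpy as np
import pytest

from pleioscan.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300 subjects x 150 SNPs, mild missingness, deterministic."""
    spec = CohortSpec(
        n_subjects=300,
        n_snps=150,
        missing_rate=0.02,
        missing_snp_fraction=0.2,
        seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
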