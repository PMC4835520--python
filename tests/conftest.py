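import numpy as np
import pytest

from ampliqc.synthdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    """A small cohort configuration used across unit tests (default error
    structure, reduced sizes)."""
    return SimConfig(
        seed=5,
        genome_length=220_000,
        n_exons=240,
        n_truth_snps=300,
        n_truth_indels=60,
        n_samples=3,
        fp_per_sample_snp=40,
        fp_per_sample_indel=20,
        mean_coverage=80.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg, emit_reads=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
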