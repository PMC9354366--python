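import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=200)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_binary_matrix(rng, n_hap, n_sites):
    """Random 0/1 haplotype matrix with site frequencies spread over (0, 1)."""
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    return (rng.random((n_hap, n_sites)) < freqs).astype(np.int8)


@pytest.fixture
def small_sim():
    """Small simulated cohort with conversions, crossovers and GC bias."""
    from ncohap.synthetic_data import SimConfig, simulate

    cfg = SimConfig(seed=7, n_samples=30, region_length_bp=400_000,
                    n_archaic_snps=400, base_conversion_rate=0.002,
                    n_crossovers=2, gc_transmission_bias=0.7)
    return simulate(cfg)
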