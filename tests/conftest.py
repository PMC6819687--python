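import numpy as np
import pytest

from arraycnv.hmm_caller import CnvCall, HmmModel
from arraycnv.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def model():
    return HmmModel()


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-sized cohort: 12 samples, 1 chromosome, ~1,600 markers, 6 events."""
    cfg = SimConfig(
        n_samples=12,
        n_chromosomes=1,
        chrom_length=5_000_000,
        n_events=6,
        n_singleton_events=2,
        carriers_max=5,
        seed=42,
    )
    marker_map, signal, genotypes, truth = simulate_cohort(cfg)
    return cfg, marker_map, signal, genotypes, truth


def make_call(
    start, end, sample="A", cn=3, chrom="chr1", num_snps=3, confidence=1.0
) -> CnvCall:
    return CnvCall(sample, chrom, start, end, cn, f"CN{cn}", num_snps, confidence)
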