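import pytest

from strainmeth import pipeline as pl
from strainmeth.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated WT sample, shared across module tests."""
    cfg = SimulationConfig(
        n_autosomes=1,
        chrom_length=100_000,
        include_X=False,
        n_genes_per_chrom=8,
        coverage=10,
        seed=3,
    )
    return pl.simulate_sample(cfg)


@pytest.fixture(scope="session")
def small_result(small_sim):
    return pl.process_sample(small_sim, use_aligner=False)
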