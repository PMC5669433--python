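import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_cohort():
    """Single-SNP cohort with the carrier-stratified IL-6 slopes used
    throughout the stratified-regression tests."""
    from fibsnp import simulate as sim

    cfg = sim.interaction_recovery_config(n_samples=800, seed=11)
    return sim.simulate_cohort(cfg, seed=11)
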