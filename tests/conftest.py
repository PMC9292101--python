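import numpy as np
import pytest

from syncsl import stimgen, synthdata


@pytest.fixture(scope="session")
def language():
    pools = stimgen.default_language_pools()
    return stimgen.build_language(list(pools["L1"]), seed=7)


@pytest.fixture(scope="session")
def behavior_data():
    """Default-pattern behavioral cohort (23 high / 32 low, 16 trials/cond)."""
    data, truth = synthdata.simulate_behavior(synthdata.BehaviorGenParams(seed=11))
    return data, truth


@pytest.fixture(scope="session")
def small_bold():
    """Six-subject planted-network BOLD cohort on a desk-scale grid."""
    params = synthdata.BoldGenParams(
        n_subjects=6, grid_shape=(12, 12, 8), noise_sd=0.5, seed=5
    )
    return synthdata.simulate_bold(params)
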