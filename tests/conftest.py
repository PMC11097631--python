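import numpy as np
import pytest

from acmap import synth
from acmap.protocol import pt_grid_protocol


@pytest.fixture(scope="session")
def pt_protocol():
    return pt_grid_protocol(n_repetitions=10)


@pytest.fixture(scope="session")
def small_protocol():
    return pt_grid_protocol(n_repetitions=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_peak_population():
    cfg = synth.SynthConfig(
        n_neurons=40, rng_seed=7, trial_noise_sd=0.0, class_fractions=(1.0, 0.0, 0.0)
    )
    recs, truth = synth.generate_population(cfg)
    return cfg, recs, truth
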