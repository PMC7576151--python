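import numpy as np
import pytest

import habmosaic as hm
import habmosaic.synth as synth


@pytest.fixture(scope="session")
def small_sim_config():
    return synth.SimConfig(nrows=60, ncols=60, n_animals=10, seed=3)


@pytest.fixture(scope="session")
def small_landscape(small_sim_config):
    return synth.make_landscape(small_sim_config)


@pytest.fixture(scope="session")
def small_telemetry(small_landscape, small_sim_config):
    return synth.simulate_telemetry(small_landscape, small_sim_config)


@pytest.fixture(scope="session")
def screened_presence_xy(small_landscape, small_telemetry):
    kept, _ = hm.screen_fixes(small_telemetry)
    kept = hm.subsample_all(kept, 5)
    return np.array([[f.x, f.y] for f in kept])


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    stack = hm.build_stack(small_landscape)
    hm.correlation_screen(stack)
    return stack
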