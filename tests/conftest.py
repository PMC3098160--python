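import numpy as np
import pytest

from grninfer import (
    average_replicates,
    extract_subnetwork,
    generate_source_topology,
    interpolate_timecourse,
    sample_kinetics,
    simulate_knockout_compendium,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def source_net():
    return generate_source_topology(40, avg_degree=2.0, activation_fraction=0.6, seed=5)


@pytest.fixture(scope="session")
def small_net(source_net):
    return extract_subnetwork(source_net, 10, seed=6)


@pytest.fixture(scope="session")
def small_model(small_net):
    return sample_kinetics(small_net, seed=7)


@pytest.fixture(scope="session")
def small_timecourse(small_model):
    return simulate_timecourse(small_model, seed=8)


@pytest.fixture(scope="session")
def small_series(small_timecourse):
    return interpolate_timecourse(average_replicates(small_timecourse))


@pytest.fixture(scope="session")
def steady_panel(small_model):
    return simulate_knockout_compendium(
        small_model, mode="steady", noise_level=0.05, seed=9
    )


@pytest.fixture(scope="session")
def timecourse_panel(small_model):
    return simulate_knockout_compendium(
        small_model, mode="timecourse", noise_level=0.05, seed=9
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
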