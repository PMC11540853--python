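import numpy as np
import pytest

import tempograph as tg
from tempograph import pipeline, preprocess, tuning


@pytest.fixture(scope="session")
def pyramid():
    return tg.build_pyramid()


@pytest.fixture(scope="session")
def diamond():
    return tg.build_diamond()


@pytest.fixture(scope="session")
def planted_session(pyramid):
    """One simulated session with the default (remapping) schedules."""
    cfg = tg.SimulationConfig(
        n_neurons={"H": 16, "EC": 12, "other": 8}, break_duration=40.0, seed=11
    )
    return tg.simulate_session(cfg, pyramid)


@pytest.fixture(scope="session")
def null_session(pyramid):
    """Static-tuning session: flat learning schedules, nothing remaps."""
    from tempograph.synthdata import simulate_null_session

    cfg = tg.SimulationConfig(
        n_neurons={"H": 16, "EC": 12, "other": 8}, break_duration=40.0, seed=12
    )
    return simulate_null_session(cfg, pyramid)


@pytest.fixture(scope="session")
def successor_session(pyramid):
    """Session whose tuning spread is graded by successor (e^A) closeness.

    The spread tops out well below the concurrent preferred gain (0.35 vs
    0.7): with near-equal gains the representations of adjacent nodes merge
    and the population geometry degenerates, whereas decoded posteriors for
    the actually presented stimulus should stay dominant throughout.
    """
    cfg = tg.SimulationConfig(
        n_neurons={"H": 40, "EC": 30}, remap_profile="successor",
        break_duration=20.0, seed=21,
        selectivity_decay_schedule=(1, 0.95, 0.9, 0.85, 0.8, 0.75, 0.7, 0.7),
        direct_gain_schedule=(0, 0.05, 0.1, 0.15, 0.25, 0.3, 0.35, 0.35),
    )
    return tg.simulate_session(cfg, pyramid)


@pytest.fixture(scope="session")
def planted_binned(planted_session):
    b = preprocess.preprocess(planted_session.spikes, planted_session.events, "selection")
    return pipeline.drop_first_trial_per_phase(b)


@pytest.fixture(scope="session")
def planted_labels(planted_binned, pyramid, planted_session):
    return tuning.classify_neurons(planted_binned, pyramid, planted_session.neuron_info())


def ground_truth_map(session):
    return {n["neuron"]: n for n in session.ground_truth["neurons"]}
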