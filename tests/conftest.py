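import numpy as np
import pytest

from attndose.core import SessionSpec
from attndose.synthetic import (
    BehaviorModel,
    EnsembleSpec,
    NeuronSpec,
    simulate_session,
    tuned_ensemble,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ensemble(rng):
    """10 tuned neurons, 2 per electrode, modest shared noise."""
    return tuned_ensemble(10, rng, untuned_fraction=0.0, latent_sd=0.15)


@pytest.fixture
def placebo_spec():
    return SessionSpec(subject_id="S1", session_index=0, treatment="placebo")


@pytest.fixture
def small_session(placebo_spec, small_ensemble):
    return simulate_session(
        placebo_spec,
        small_ensemble,
        BehaviorModel(hit_probability=0.85),
        seed=7,
        n_trials=240,
    )


def single_neuron_ensemble(
    baseline=20.0,
    preferred=2,
    visual_gain=1.0,
    attention_gain=1.0,
    saccade_gain=1.0,
    latency=50.0,
    loading=0.0,
):
    spec = NeuronSpec(
        neuron_id="n000",
        electrode_id="e000",
        baseline_rate=baseline,
        preferred_quadrant=preferred,
        visual_gain=visual_gain,
        attention_gain=attention_gain,
        saccade_gain=saccade_gain,
        response_latency_ms=latency,
    )
    return EnsembleSpec(neurons=[spec], latent_loadings=[loading])
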