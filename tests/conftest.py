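"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from habclust.io_formats import RunConfig, SpikeTrain
from habclust.pipeline import cluster_dataset
from habclust.synthetic import generate_population, preset_specs


def make_train(times, duration=None, neuron_id="n0", **kwargs) -> SpikeTrain:
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = float(times[-1] + 1.0) if times.size else 1.0
    return SpikeTrain(neuron_id=neuron_id, spike_times=times, duration=duration, **kwargs)


def random_train(rng: np.random.Generator, n_spikes: int, duration: float = 20.0) -> SpikeTrain:
    times = np.sort(rng.uniform(0, duration, size=n_spikes))
    times = np.unique(times)
    return make_train(times, duration=duration)


def poisson_train(rng: np.random.Generator, rate: float, duration: float) -> SpikeTrain:
    isis = rng.exponential(1.0 / rate, size=int(rate * duration * 1.5) + 50)
    t = np.cumsum(isis)
    return make_train(t[t < duration], duration=duration)


def regular_train(rate: float, duration: float) -> SpikeTrain:
    t = np.arange(1, int(rate * duration)) / rate
    return make_train(t[t < duration], duration=duration)


@pytest.fixture(scope="session")
def preset_population():
    """A 4-type anesthetized population with ground-truth labels.

    The population size matches the scale the mixture model needs to
    estimate full covariances in 19 dimensions; recordings are kept
    short to bound test runtime.
    """
    specs = preset_specs("anesthetized")
    dataset, labels = generate_population(specs, n_per_type=70, duration=90.0, seed=11)
    return dataset, labels


@pytest.fixture(scope="session")
def clustered_population(preset_population):
    """The preset population clustered with a reduced restart budget."""
    dataset, labels = preset_population
    cfg = RunConfig(seed=11, k_max=6, n_restarts=15)
    table, model = cluster_dataset(dataset.trains, cfg)
    return dataset, labels, table, model
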