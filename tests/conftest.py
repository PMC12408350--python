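"""Shared fixtures: small grids, toy models and fabricated spike data."""

import numpy as np
import pytest

from latentspike.data import SpikeData, Trial
from latentspike.grid import build_grid
from latentspike.model import LatentModel


@pytest.fixture(scope="session")
def grid64():
    return build_grid(64)


@pytest.fixture(scope="session")
def grid32():
    return build_grid(32)


@pytest.fixture()
def toy_model(grid64):
    """Two conditions, two neurons, smooth non-trivial components."""
    g = grid64
    return LatentModel(
        grid=g,
        forces=np.vstack([1.5 * np.sin(2 * g.nodes), -1.0 * g.nodes]),
        D=0.4,
        F0=0.8 * np.cos(3 * g.nodes),
        tuning_aux=np.vstack([0.7 * np.ones(g.n), -0.5 * g.nodes]),
        tuning_C=np.array([8.0, 15.0]),
    )


def fabricate_trials(rng, n_trials=6, n_neurons=2, n_conditions=2, max_spikes=6):
    """Hand-made trials with ordered random spikes (not model-generated)."""
    trials = []
    for k in range(n_trials):
        dur = 0.3 + 0.2 * rng.random()
        ns = int(rng.integers(1, max_spikes))
        st = np.sort(rng.random(ns)) * dur * 0.9 + 0.02
        ids = rng.integers(0, n_neurons, ns)
        trials.append(
            Trial(0.0, dur, st, ids, condition=int(k % n_conditions), choice=1)
        )
    return trials


@pytest.fixture()
def toy_data(toy_model):
    rng = np.random.default_rng(7)
    return SpikeData(fabricate_trials(rng, n_trials=8), toy_model.n_neurons)
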