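"""Shared fixtures: physics objects, the benchmark geometry, and simulated
crossing-statistics datasets reused across test modules (session-scoped so
the Brownian-dynamics work is done once)."""

import numpy as np
import pytest

import spherokin as sk


@pytest.fixture(scope="session")
def uncharged():
    return sk.uncharged_reference()


@pytest.fixture(scope="session")
def charged():
    return sk.charged_reference()


@pytest.fixture(scope="session")
def network():
    return sk.benchmark_network()


def _simulate(physics, seed, n_fhpd=400, n_traj=800):
    spec = sk.BDSystemSpec(physics=physics, seed=seed)
    net = spec.network
    fhpd = {m: sk.sample_fhpd(spec, m, n_fhpd)
            for m in range(net.n) if m not in net.sink_indices}
    stats, events = sk.run_milestoning_trajectories(spec, fhpd, n_traj)
    return spec, fhpd, stats, events


@pytest.fixture(scope="session")
def uncharged_dataset(uncharged):
    """(spec, fhpd, stats, events) for the uncharged benchmark system."""
    return _simulate(uncharged, seed=101)


@pytest.fixture(scope="session")
def charged_dataset(charged):
    """(spec, fhpd, stats, events) for the charged benchmark system."""
    return _simulate(charged, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251002)
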