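"""Small deterministic fixture datasets for tests, demos and format checks.

Three named fixtures are provided:

* ``uncharged_sphere`` / ``charged_sphere`` — crossing events simulated with
  the Brownian-dynamics engine on the six-milestone spherical-receptor
  geometry.  Milestone trajectories are launched from uniform points on
  each sphere, which *is* the first-hitting point distribution for a
  central potential (isotropy), so fixture generation stays cheap.
* ``two_site_toy`` — events sampled from a hand-specified Markov chain with
  two bound sinks on distinct branches sharing a hub milestone, emulating a
  receptor with two competing binding sites.  It exercises the multi-sink
  bookkeeping (beta = sum of per-site absorption probabilities) without any
  protein input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bd import (BDSystemSpec, run_milestoning_trajectories,
                 uniform_sphere_points)
from .io import RunConfig, save_config, write_crossing_events
from .network import concentric_network
from .physics import charged_reference, uncharged_reference

FIXTURE_NAMES = ("uncharged_sphere", "charged_sphere", "two_site_toy")

# ground truth of the two-site toy chain: states 0,1 bound sinks,
# 2,3 branch midpoints, 4 hub (b-surface), 5 escape
_TOY_K = {
    2: {0: 0.5, 4: 0.5},
    3: {1: 0.4, 4: 0.6},
    4: {2: 0.3, 3: 0.3, 5: 0.4},
}
_TOY_MEAN_T = {2: 1.0, 3: 1.5, 4: 2.0}
_TOY_N_PER_STATE = 400


def _sphere_config(charged: bool, seed: int, n: int) -> RunConfig:
    return RunConfig.model_validate({
        "physics": (
            {"kind": "coulomb", "Q_c": -1.0, "Q_s": 1.0, "eps_r": 92.0,
             "T": 300.0, "D_cm2_s": 1.33e-5}
            if charged else
            {"kind": "none", "T": 300.0, "D_cm2_s": 1.33e-5}
        ),
        "geometry": {"radii": [6.0, 7.0, 8.0, 9.0, 10.0, 11.0],
                     "bound": [6.0], "escape": 11.0, "b_radius": 10.0},
        "simulation": {"dt": 0.01, "n": n, "seed": seed},
    })


def _sphere_fixture(charged: bool, seed: int, n_per: int):
    physics = charged_reference() if charged else uncharged_reference()
    network = concentric_network([6, 7, 8, 9, 10, 11], bound=6.0,
                                 escape=11.0, b_radius=10.0)
    spec = BDSystemSpec(physics=physics, network=network, seed=seed)
    rng = np.random.default_rng(seed)
    fhpd = {
        m: uniform_sphere_points(n_per, network.radii[m], rng)
        for m in range(network.n) if m not in network.sink_indices
    }
    _, events = run_milestoning_trajectories(spec, fhpd, n_per)
    return _sphere_config(charged, seed, n_per), events


def toy_chain_truth() -> dict:
    """Exact absorption probabilities of the two-site toy chain from its
    hub, per bound site and total (fundamental-matrix arithmetic on the
    specified kernel)."""
    n = 6
    K = np.zeros((n, n))
    for i, row in _TOY_K.items():
        for j, p in row.items():
            K[i, j] = p
    trans = [2, 3, 4]
    A = np.eye(3) - K[np.ix_(trans, trans)]
    probs = {}
    for site in (0, 1):
        b = K[trans, site]
        h = np.linalg.solve(A, b)
        probs[str(site)] = float(h[trans.index(4)])
    probs["beta"] = probs["0"] + probs["1"]
    return probs


def _toy_fixture(seed: int):
    rng = np.random.default_rng(seed)
    src, dst, tt = [], [], []
    for i, row in _TOY_K.items():
        dests = np.array(list(row))
        probs = np.array([row[d] for d in dests])
        picks = rng.choice(dests, size=_TOY_N_PER_STATE, p=probs)
        times = rng.exponential(_TOY_MEAN_T[i], size=_TOY_N_PER_STATE)
        src.extend([i] * _TOY_N_PER_STATE)
        dst.extend(int(d) for d in picks)
        tt.extend(times.round(6))
    events = pd.DataFrame({
        "traj_id": np.arange(len(src)),
        "src_milestone": src,
        "dst_milestone": dst,
        "transit_time_ps": tt,
    })
    config = RunConfig.model_validate({
        "physics": {"kind": "none", "T": 300.0, "D_cm2_s": 1.33e-5},
        "geometry": {"radii": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                     "bound": [1.0, 2.0], "escape": 6.0, "b_radius": 5.0},
        "simulation": {"seed": seed, "n": _TOY_N_PER_STATE},
    })
    return config, events


def make_fixture(name: str, seed: int, outdir, n_per: int = 150) -> Path:
    """Write a deterministic fixture (config.yaml + events.tsv) and return
    its directory.  ``name`` is one of FIXTURE_NAMES."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    out = Path(outdir) / name
    out.mkdir(parents=True, exist_ok=True)
    if name == "two_site_toy":
        config, events = _toy_fixture(seed)
        with open(out / "truth.json", "w") as fh:
            json.dump(toy_chain_truth(), fh, indent=2, sort_keys=True)
    else:
        config, events = _sphere_fixture(name == "charged_sphere", seed, n_per)
    save_config(config, out / "config.yaml")
    write_crossing_events(events, out / "events.tsv")
    return out
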