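"""Configuration, crossing-event TSV format, and results serialization.

The on-disk event format is a TSV with header
``traj_id  src_milestone  dst_milestone  transit_time_ps``; milestone
indices are 0-based from the innermost surface outward.  Results are a
single JSON document carrying beta, k_on, MFPT, the free-energy profile,
credible intervals, and a provenance block (resolved config, its hash, the
seed, and the pinned physical constants) sufficient to regenerate the run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .bd import EVENT_COLUMNS, BDSystemSpec
from .milestoning import RateEstimate, TransitionStatistics
from .network import MilestoneNetwork, concentric_network
from .physics import CentralPotential


class PhysicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "none"
    Q_c: float = 0.0
    Q_s: float = 0.0
    eps_r: float = 78.0
    T: float = 300.0
    D_cm2_s: float = 1.0e-5

    def build(self) -> CentralPotential:
        return CentralPotential(**self.model_dump())


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radii: list[float]
    bound: list[float]
    escape: float
    b_radius: Optional[float] = None

    def build(self) -> MilestoneNetwork:
        return concentric_network(self.radii, self.bound, self.escape,
                                  self.b_radius)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt: float = 0.01
    n: int = 1000
    seed: int = 0
    max_steps: int = 1_000_000


class ExternalConfig(BaseModel):
    """Externally supplied arrival rates (e.g. from an imported BD regime)."""
    model_config = ConfigDict(extra="forbid")
    k_b: Optional[float] = None  # M^-1 s^-1
    k_q: Optional[float] = None  # M^-1 s^-1


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    physics: PhysicsConfig = Field(default_factory=PhysicsConfig)
    geometry: GeometryConfig
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    external: ExternalConfig = Field(default_factory=ExternalConfig)

    def build_spec(self) -> BDSystemSpec:
        return BDSystemSpec(physics=self.physics.build(),
                            network=self.geometry.build(),
                            dt=self.simulation.dt,
                            seed=self.simulation.seed,
                            max_steps=self.simulation.max_steps)

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


def read_crossing_events(path, network: MilestoneNetwork | None = None,
                         n_milestones: int | None = None,
                         ) -> tuple[TransitionStatistics, pd.DataFrame]:
    """Read a crossing-event TSV and accumulate transition statistics.

    Malformed rows are reported with their 1-based file line numbers.  An
    empty file yields empty statistics with a warning.
    """
    if network is not None:
        n_milestones = network.n
    if n_milestones is None:
        raise ValueError("a network or milestone count is required")
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(EVENT_COLUMNS):
        raise ValueError(
            f"{path}: expected header {list(EVENT_COLUMNS)}, got {list(df.columns)}")
    if df.empty:
        warnings.warn(f"{path}: no crossing events", stacklevel=2)
        return TransitionStatistics.empty(n_milestones), df

    bad: list[str] = []
    src = df["src_milestone"].to_numpy()
    dst = df["dst_milestone"].to_numpy()
    tt = df["transit_time_ps"].to_numpy()
    for mask, msg in [
        ((src < 0) | (src >= n_milestones) | (dst < 0) | (dst >= n_milestones),
         "milestone index outside the configured network"),
        (tt < 0, "negative transit time"),
        (src == dst, "self-transition"),
    ]:
        for i in np.flatnonzero(mask):
            bad.append(f"line {i + 2}: {msg}")  # +2: header + 1-based
    if bad:
        raise ValueError(f"{path}: " + "; ".join(bad[:20]))
    stats = TransitionStatistics.from_events(n_milestones, src, dst, tt)
    return stats, df


def write_crossing_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, columns=list(EVENT_COLUMNS))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return [None if (isinstance(v, float) and not np.isfinite(v)) else v
                for v in x.tolist()]
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def results_document(estimate: RateEstimate,
                     config: RunConfig | None = None,
                     seed: int | None = None,
                     event_counts: Sequence[int] | None = None,
                     extra: dict | None = None) -> dict:
    """Assemble the single-JSON results document with provenance."""
    doc = {
        "beta": _jsonable(estimate.beta),
        "kon_M1s1": _jsonable(estimate.kon),
        "mfpt_ps": _jsonable(estimate.mfpt),
        "dG_kcal_mol": _jsonable(estimate.dG) if estimate.dG is not None else None,
        "confidence_level": estimate.level,
        "intervals": {
            k: [_jsonable(v[0]), _jsonable(v[1])]
            for k, v in estimate.intervals.items()
        },
        "provenance": {
            "package": "spherokin",
            "version": __version__,
            "seed": seed,
            "config": config.model_dump() if config is not None else None,
            "config_hash": config.hash() if config is not None else None,
            "event_counts": [int(c) for c in event_counts] if event_counts is not None else None,
        },
    }
    if config is not None:
        doc["provenance"]["constants"] = config.physics.build().provenance()["constants"]
    if extra:
        doc.update(extra)
    return doc


def save_results(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
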