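"""Milestone geometry: ordered concentric spherical surfaces with roles.

Milestone indexing is 0-based from the innermost surface outward, so that
nearest-neighbour assumptions are auditable from the radii alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

ROLES = ("bound", "intermediate", "escape")


@dataclass(frozen=True)
class Milestone:
    index: int
    radius: float  # angstrom
    role: str


@dataclass(frozen=True)
class MilestoneNetwork:
    """Ordered set of concentric milestones.

    ``b_index`` marks the surface where external flux k_b is delivered
    (trajectories "start on the b-surface"); ``q_index`` marks the escape
    surface beyond which a ligand is deemed lost to bulk.
    """

    milestones: tuple[Milestone, ...]
    b_index: int
    q_index: int

    def __post_init__(self) -> None:
        ms = self.milestones
        if len(ms) < 2:
            raise ValueError("need at least two milestones")
        radii = [m.radius for m in ms]
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError("milestone radii must be strictly increasing")
        for m in ms:
            if m.role not in ROLES:
                raise ValueError(f"unknown role {m.role!r}")
        escapes = [m for m in ms if m.role == "escape"]
        if len(escapes) != 1:
            raise ValueError("exactly one escape milestone required")
        bounds = [m for m in ms if m.role == "bound"]
        if not bounds:
            raise ValueError("at least one bound milestone required")
        if max(b.radius for b in bounds) >= escapes[0].radius:
            raise ValueError("bound radii must lie below the escape radius")
        inter = [m for m in ms if m.role == "intermediate"]
        if inter:
            if max(b.radius for b in bounds) >= min(i.radius for i in inter):
                raise ValueError("bound radii must lie below all intermediates")
            if max(i.radius for i in inter) >= escapes[0].radius:
                raise ValueError("intermediate radii must lie below the escape radius")
        if not (0 <= self.b_index < len(ms)):
            raise ValueError("b_index out of range")
        if self.q_index != escapes[0].index:
            raise ValueError("q_index must point at the escape milestone")

    @property
    def n(self) -> int:
        return len(self.milestones)

    @property
    def radii(self) -> tuple[float, ...]:
        return tuple(m.radius for m in self.milestones)

    @property
    def bound_indices(self) -> tuple[int, ...]:
        return tuple(m.index for m in self.milestones if m.role == "bound")

    @property
    def sink_indices(self) -> tuple[int, ...]:
        """Bound milestones plus the escape surface: the absorbing set."""
        return tuple(sorted(self.bound_indices + (self.q_index,)))

    @property
    def reaction_radius(self) -> float:
        """Innermost bound radius (the reaction surface a)."""
        return min(m.radius for m in self.milestones if m.role == "bound")

    @property
    def b_radius(self) -> float:
        return self.milestones[self.b_index].radius

    @property
    def q_radius(self) -> float:
        return self.milestones[self.q_index].radius

    def to_dict(self) -> dict:
        return {
            "milestones": [
                {"index": m.index, "radius_A": m.radius, "role": m.role}
                for m in self.milestones
            ],
            "b_index": self.b_index,
            "q_index": self.q_index,
        }


def concentric_network(radii: Sequence[float],
                       bound: Sequence[float] | float,
                       escape: float,
                       b_radius: float | None = None) -> MilestoneNetwork:
    """Build a network from radii, designating bound/escape surfaces.

    Parameters
    ----------
    radii : increasing radii in angstrom (must include bound and escape).
    bound : radius (or radii) of the bound surface(s).
    escape : radius of the escape surface.
    b_radius : radius of the b-surface; defaults to the outermost
        non-escape milestone.
    """
    bound_set = {bound} if isinstance(bound, (int, float)) else set(bound)
    radii = sorted(radii)
    ms = []
    for i, r in enumerate(radii):
        if r in bound_set:
            role = "bound"
        elif r == escape:
            role = "escape"
        else:
            role = "intermediate"
        ms.append(Milestone(index=i, radius=float(r), role=role))
    if b_radius is None:
        b_radius = radii[-2]
    b_index = radii.index(b_radius)
    q_index = radii.index(escape)
    return MilestoneNetwork(milestones=tuple(ms), b_index=b_index, q_index=q_index)


def benchmark_network() -> MilestoneNetwork:
    """The six-milestone spherical-receptor geometry: reaction surface at
    6 A, intermediates at 7-10 A, escape at 11 A, b-surface at 10 A."""
    return concentric_network(
        radii=[6.0, 7.0, 8.0, 9.0, 10.0, 11.0],
        bound=6.0, escape=11.0, b_radius=10.0,
    )
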