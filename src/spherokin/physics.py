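"""Radial physics of a point ligand diffusing in a central potential.

`CentralPotential` bundles the charges, dielectric, temperature and
diffusion coefficient of a spherically symmetric system and exposes the
reduced potential U(r)/k_B T together with the Onsager length

    r_c = Q_c Q_s e^2 / (4 pi eps0 eps_r k_B T)

which sets the distance at which the Coulomb energy equals thermal energy.
r_c is kept *signed*: negative for attraction (opposite charges), positive
for repulsion, zero for an uncharged receptor.  With that convention
U(r)/k_B T = r_c / r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as C


@dataclass(frozen=True)
class CentralPotential:
    """Physics of a radial ligand-receptor system.

    Parameters
    ----------
    kind : {"none", "coulomb"}
        Shape of the effective interaction.
    Q_c, Q_s : float
        Central (receptor) and substrate charge, in units of e.  Ignored
        for ``kind="none"``.
    eps_r : float
        Relative dielectric of the solvent continuum.
    T : float
        Temperature, kelvin.
    D_cm2_s : float
        Translational diffusion coefficient of the substrate, cm^2/s.
    """

    kind: str = "none"
    Q_c: float = 0.0
    Q_s: float = 0.0
    eps_r: float = 78.0
    T: float = 300.0
    D_cm2_s: float = 1.0e-5
    D: float = field(init=False)  # A^2/ps

    def __post_init__(self) -> None:
        if self.kind not in ("none", "coulomb"):
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.eps_r <= 0:
            raise ValueError("eps_r must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.D_cm2_s <= 0:
            raise ValueError("D must be positive")
        object.__setattr__(self, "D", self.D_cm2_s * C.CM2_PER_S_TO_A2_PER_PS)

    @property
    def onsager_length(self) -> float:
        """Signed Onsager length r_c in angstrom (0 for kind='none')."""
        if self.kind == "none":
            return 0.0
        rc_m = (
            self.Q_c
            * self.Q_s
            * C.ELEMENTARY_CHARGE_C**2
            / (4.0 * math.pi * C.VACUUM_PERMITTIVITY * self.eps_r
               * C.BOLTZMANN_J_PER_K * self.T)
        )
        return rc_m * C.METER_TO_ANGSTROM

    def reduced_potential(self, r: float) -> float:
        """U(r) / k_B T at radius r (angstrom)."""
        if r <= 0:
            raise ValueError("r must be positive")
        rc = self.onsager_length
        return rc / r if rc != 0.0 else 0.0

    def reduced_force_radial(self, r: float) -> float:
        """Radial component of F/(k_B T) = -d(U/k_B T)/dr, in 1/angstrom.

        Negative values point inward (attraction).
        """
        rc = self.onsager_length
        return rc / (r * r) if rc != 0.0 else 0.0

    def provenance(self) -> dict:
        return {
            "kind": self.kind,
            "Q_c_e": self.Q_c,
            "Q_s_e": self.Q_s,
            "eps_r": self.eps_r,
            "T_K": self.T,
            "D_cm2_s": self.D_cm2_s,
            "D_A2_ps": self.D,
            "onsager_length_A": self.onsager_length,
            "constants": C.constants_provenance(),
        }


def uncharged_reference(D_cm2_s: float = 1.33e-5, T: float = 300.0) -> CentralPotential:
    """The uncharged spherical-receptor benchmark system (Na+ in water)."""
    return CentralPotential(kind="none", T=T, D_cm2_s=D_cm2_s)


def charged_reference(D_cm2_s: float = 1.33e-5, T: float = 300.0,
                      eps_r: float = 92.0) -> CentralPotential:
    """The charged spherical-receptor benchmark: +1e substrate attracted by
    a central -1e charge in a dielectric matching TIP3P-like water."""
    return CentralPotential(kind="coulomb", Q_c=-1.0, Q_s=+1.0,
                            eps_r=eps_r, T=T, D_cm2_s=D_cm2_s)
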