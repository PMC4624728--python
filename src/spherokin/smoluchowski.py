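"""Closed-form and quadrature solutions of the radial Smoluchowski problem.

For a point ligand diffusing in a central potential U(r) with constant
diffusion coefficient D, the steady-state theory of diffusion-limited
reactions gives:

* the rate of first arrival at a sphere of radius b from bulk,
      k(b) = 4 pi [ integral_b^inf  e^{U(r)/kT} / (r^2 D(r)) dr ]^-1,
  which reduces to 4 pi b D for U = 0 and to the classic Debye result
  4 pi D r_c / (e^{r_c/b} - 1) for a bare Coulomb potential with signed
  Onsager length r_c;

* the splitting probability (committor) of reaching an inner absorber at a
  before an outer absorber at q from a start radius s,
      beta = [W(q) - W(s)] / [W(q) - W(a)],
  with W an antiderivative of e^{U/kT} / r^2 (W = -1/r for U = 0 and
  W = -e^{r_c/r}/r_c for Coulomb);

* the mean first passage time to the absorber pair {a, q} of a particle
  injected on the sphere r = source, obtained from the stationary density
  u(r) of a unit-source problem as tau = N / J with N the number of
  particles in the domain and J the total absorbed current.

All radii in angstrom; bimolecular rates returned in M^-1 s^-1 and times
in ps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from . import constants as C
from .physics import CentralPotential

_QUAD_RTOL = 1e-10


def rate_volume_to_molar(k: float, unit: str = "cm3/s") -> float:
    """Convert a per-molecule volume rate to a molar rate constant.

    ``unit`` is 'cm3/s' or 'A3/ps'.
    """
    if k < 0:
        raise ValueError("rate must be non-negative")
    if unit == "cm3/s":
        return k * C.CM3_PER_S_TO_PER_M_PER_S
    if unit == "A3/ps":
        return k * C.A3_PER_PS_TO_CM3_PER_S * C.CM3_PER_S_TO_PER_M_PER_S
    raise ValueError(f"unknown unit tag {unit!r}")


def rate_molar_to_volume(k: float, unit: str = "cm3/s") -> float:
    """Inverse of :func:`rate_volume_to_molar`."""
    if k < 0:
        raise ValueError("rate must be non-negative")
    if unit == "cm3/s":
        return k / C.CM3_PER_S_TO_PER_M_PER_S
    if unit == "A3/ps":
        return k / (C.A3_PER_PS_TO_CM3_PER_S * C.CM3_PER_S_TO_PER_M_PER_S)
    raise ValueError(f"unknown unit tag {unit!r}")


def k_free(r: float, physics: CentralPotential) -> float:
    """Smoluchowski rate 4 pi r D onto an absorbing sphere, M^-1 s^-1."""
    if r <= 0:
        raise ValueError("r must be positive")
    return rate_volume_to_molar(4.0 * math.pi * r * physics.D, "A3/ps")


def k_coulomb(r: float, physics: CentralPotential) -> float:
    """Debye rate onto an absorbing sphere in a bare Coulomb potential.

    Continuous in the charges: the r_c -> 0 limit is k_free(r).
    Overflow-safe for strongly repulsive systems (|r_c|/r large).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    rc = physics.onsager_length
    if rc == 0.0:
        return k_free(r, physics)
    x = rc / r
    if x > 700.0:  # exp would overflow; rate is exponentially suppressed
        k_vol = 4.0 * math.pi * physics.D * rc * math.exp(-x)
    else:
        k_vol = 4.0 * math.pi * physics.D * rc / math.expm1(x)
    return rate_volume_to_molar(k_vol, "A3/ps")


def k_general(b: float, physics: CentralPotential,
              U_over_kT: Callable[[float], float] | None = None,
              D_of_r: Callable[[float], float] | None = None) -> float:
    """Arrival rate at radius b for arbitrary radial U(r) and D(r).

    Evaluates 4 pi [ int_b^inf e^{U/kT} / (r^2 D) dr ]^-1 by adaptive
    quadrature.  ``U_over_kT`` defaults to the physics object's reduced
    potential; ``D_of_r`` defaults to the constant stored D (A^2/ps).
    A divergent integral (potential not decaying) is reported as a zero
    rate with a warning.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    if U_over_kT is None:
        U_over_kT = physics.reduced_potential
    if D_of_r is None:
        D_of_r = lambda r: physics.D  # noqa: E731

    # substitute x = 1/r: int_b^inf e^{U}/(r^2 D) dr = int_0^{1/b} e^{U(1/x)}/D(1/x) dx,
    # a finite-interval integral (the x -> 0 endpoint is the decayed-potential bulk)
    def integrand(x: float) -> float:
        if x == 0.0:
            return 1.0 / D_of_r(1e30)
        r = 1.0 / x
        return math.exp(U_over_kT(r)) / D_of_r(r)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            body, _ = quad(integrand, 0.0, 1.0 / b, epsrel=_QUAD_RTOL, limit=200)
    except Exception as exc:  # divergent or non-convergent integral
        warnings.warn(f"rate integral did not converge ({exc}); reporting 0",
                      stacklevel=2)
        return 0.0
    if not math.isfinite(body) or body <= 0:
        warnings.warn("rate integral divergent; reporting 0", stacklevel=2)
        return 0.0
    k_vol = 4.0 * math.pi / body
    return rate_volume_to_molar(k_vol, "A3/ps")


def _W(r: float, rc: float) -> float:
    """Antiderivative of e^{U/kT}/r^2 for U/kT = rc/r (rc = 0 -> free)."""
    if rc == 0.0:
        return -1.0 / r
    return -math.exp(rc / r) / rc


def splitting_probability(a: float, start: float, q: float,
                          physics: CentralPotential) -> float:
    """Probability of absorbing at the inner sphere a before the outer
    sphere q, starting from radius ``start`` (the radial committor)."""
    if not (a < start < q) and start not in (a, q):
        raise ValueError("require a <= start <= q with a < q")
    if start == a:
        return 1.0
    if start == q:
        return 0.0
    rc = physics.onsager_length
    return (_W(q, rc) - _W(start, rc)) / (_W(q, rc) - _W(a, rc))


@dataclass(frozen=True)
class SteadyStateSolution:
    """Stationary unit-source solution between two absorbers.

    ``u`` is the stationary density profile (callable of r), ``J_a`` and
    ``J_q`` the absorbed currents at the inner and outer boundary (they sum
    to the unit source strength), and ``N`` the particle-number integral.
    """

    a: float
    source: float
    q: float
    J_a: float
    J_q: float
    N: float
    u: Callable[[float], float]

    @property
    def mfpt(self) -> float:
        return self.N / (self.J_a + self.J_q)


def steady_state_solution(a: float, source: float, q: float,
                          physics: CentralPotential) -> SteadyStateSolution:
    """Solve the radial steady-state problem with a delta source.

    Particles are injected at unit rate uniformly on the sphere
    r = source, absorbed at r = a and r = q.  The density is
    u(r) = e^{-U/kT} v(r) with v piecewise linear in W(r); the current
    jump at the source fixes the two branches and the inner/outer
    absorbed currents equal the committor split.
    """
    if not (a < source < q):
        raise ValueError("require a < source < q")
    rc = physics.onsager_length
    D = physics.D
    beta = splitting_probability(a, source, q, physics)
    pref = 1.0 / (4.0 * math.pi * D)

    def u(r: float) -> float:
        boltz = math.exp(-rc / r) if rc != 0.0 else 1.0
        if r <= a or r >= q:
            return 0.0
        if r <= source:
            return beta * pref * (_W(r, rc) - _W(a, rc)) * boltz
        return (1.0 - beta) * pref * (_W(q, rc) - _W(r, rc)) * boltz

    n_in, _ = quad(lambda r: 4.0 * math.pi * r * r * u(r), a, source,
                   epsrel=_QUAD_RTOL, limit=200)
    n_out, _ = quad(lambda r: 4.0 * math.pi * r * r * u(r), source, q,
                    epsrel=_QUAD_RTOL, limit=200)
    return SteadyStateSolution(a=a, source=source, q=q,
                               J_a=beta, J_q=1.0 - beta,
                               N=n_in + n_out, u=u)


def mfpt_theory(a: float, source: float, q: float,
                physics: CentralPotential) -> float:
    """Mean first passage time (ps) from the source sphere to either
    absorber, computed as N/J from the steady-state solution."""
    return steady_state_solution(a, source, q, physics).mfpt


def stokes_einstein_radius(D_cm2_s: float, T: float, eta_Pa_s: float) -> float:
    """Hydrodynamic radius r = k_B T / (6 pi eta D), in angstrom."""
    if D_cm2_s <= 0 or T <= 0 or eta_Pa_s <= 0:
        raise ValueError("inputs must be positive")
    D_m2_s = D_cm2_s * 1e-4
    r_m = C.BOLTZMANN_J_PER_K * T / (6.0 * math.pi * eta_Pa_s * D_m2_s)
    return r_m * C.METER_TO_ANGSTROM


def committor_chain(radii, physics: CentralPotential) -> np.ndarray:
    """Nearest-neighbour transition kernel between concentric milestones.

    Row i (for interior milestones) holds the continuum probabilities of
    next touching milestone i-1 versus i+1 from radius radii[i]; boundary
    rows are left zero (absorbing).  This discrete chain reproduces the
    continuum committor exactly and lets the milestoning estimator be
    validated against the closed forms.
    """
    radii = list(radii)
    n = len(radii)
    K = np.zeros((n, n))
    for i in range(1, n - 1):
        p_in = splitting_probability(radii[i - 1], radii[i], radii[i + 1], physics)
        K[i, i - 1] = p_in
        K[i, i + 1] = 1.0 - p_in
    return K
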