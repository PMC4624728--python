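"""Physical constants and unit conversions, pinned in one place.

The Table-1-style rate reproductions are sensitive at the fourth significant
digit, so every module pulls its constants from here and results carry them
in their provenance block.

Internal unit system: angstrom (length), picosecond (time), elementary
charge (charge), kelvin (temperature).  Diffusion coefficients are accepted
in cm^2/s at the API boundary and stored in A^2/ps; bimolecular rates leave
the package only in M^-1 s^-1.
"""

from __future__ import annotations

# SI values
BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602177e-19
VACUUM_PERMITTIVITY = 8.854e-12  # C^2 N^-1 m^-2
AVOGADRO = 6.02214e23

# kcal/mol per kelvin (gas constant in chemists' units), derived from the
# pinned k_B and N_A so free energies stay consistent with the rates.
KB_KCAL_PER_MOL_K = BOLTZMANN_J_PER_K * AVOGADRO / 4184.0

# 1 cm^2/s = 1e16 A^2/s = 1e4 A^2/ps
CM2_PER_S_TO_A2_PER_PS = 1.0e4

# volume rates: 1 A^3/ps = 1e-24 cm^3 / 1e-12 s = 1e-12 cm^3/s
A3_PER_PS_TO_CM3_PER_S = 1.0e-12

# 1 cm^3/s per molecule = N_A / 1000 M^-1 s^-1
CM3_PER_S_TO_PER_M_PER_S = AVOGADRO / 1000.0

METER_TO_ANGSTROM = 1.0e10


def constants_provenance() -> dict:
    """The constant set in effect, for result provenance blocks."""
    return {
        "k_B_J_per_K": BOLTZMANN_J_PER_K,
        "e_C": ELEMENTARY_CHARGE_C,
        "eps0_C2_N_m2": VACUUM_PERMITTIVITY,
        "N_A": AVOGADRO,
        "k_B_kcal_per_mol_K": KB_KCAL_PER_MOL_K,
    }
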