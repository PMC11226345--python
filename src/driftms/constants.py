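"""Physical constants used throughout the mobility calculations.

CODATA 2018 values; the Loschmidt constant ``N0`` is the buffer-gas number
density at 273.15 K and 760 Torr.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    e: float = 1.602176634e-19          # elementary charge, C
    kb: float = 1.380649e-23            # Boltzmann constant, J/K
    N0: float = 2.6867811e25            # Loschmidt constant, m^-3
    proton_mass: float = 1.007276466    # u
    amu_to_kg: float = 1.66053906660e-27

    # standard reference conditions for reduced mobility
    P_standard_torr: float = 760.0
    T_standard_K: float = 273.15


CODATA = PhysicalConstants()

#: mass difference between 13C and 12C, u — isotope stick spacing per charge
NEUTRON_SPACING = 1.0033548378

#: helium buffer-gas mass, u
HELIUM_MASS = 4.002602
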