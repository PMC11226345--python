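"""Rayleigh-limit charge screen.

The empirical de la Mora relation bounds the charge a compact globular
protein ion can carry out of an electrospray droplet:

    z_R = 0.0778 * sqrt(M_R)    (M_R in Da)

An observed charge above z_R marks a species whose conformational spread
may arise from coulombically driven gas-phase unfolding rather than
solution structure; species below the limit can be read as reporting
inherent solution conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .species import IonSpecies

__all__ = ["RAYLEIGH_COEFF", "ChargeLimitReport", "rayleigh_limit", "flag_species"]

RAYLEIGH_COEFF = 0.0778


@dataclass(frozen=True)
class ChargeLimitReport:
    label: str
    M_R: float
    z_obs: int
    z_R: float
    exceeds: bool


def rayleigh_limit(M_R: float, coeff: float = RAYLEIGH_COEFF) -> float:
    """Maximum charge z_R = coeff * sqrt(M_R) for a compact ion of mass M_R (u)."""
    if M_R <= 0:
        raise ValueError("mass must be positive")
    return coeff * math.sqrt(M_R)


def flag_species(
    species: list[IonSpecies], coeff: float = RAYLEIGH_COEFF
) -> list[ChargeLimitReport]:
    """Screen every species against its Rayleigh limit (average mass used)."""
    if not species:
        raise ValueError("species list is empty")
    out = []
    for sp in species:
        z_r = rayleigh_limit(sp.mass_avg, coeff)
        out.append(
            ChargeLimitReport(
                label=sp.label,
                M_R=sp.mass_avg,
                z_obs=sp.z,
                z_R=z_r,
                exceeds=sp.z > z_r,
            )
        )
    return out
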