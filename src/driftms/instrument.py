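"""Drift-cell instrument description and ground-truth containers for the
synthetic-data generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .constants import HELIUM_MASS
from .species import IonSpecies

__all__ = ["InstrumentConfig", "NoiseModel", "FamilyTruth", "GroundTruth"]


@dataclass(frozen=True)
class InstrumentConfig:
    """Drift-tube geometry and acquisition settings.

    Defaults emulate a 5.1 cm copper drift cell filled with ~3.5 Torr
    helium, read out at six drift voltages spanning more than a factor of
    two.  ``dead_time_coeff`` scales the m/z-dependent, voltage-invariant
    dead time (t_dead = coeff * sqrt(m/z), in microseconds);
    ``width_inflation`` multiplies the diffusion-limited peak width to
    account for gate pulse width and detector response.
    """

    drift_length: float = 5.1          # cm
    pressure: float = 3.5              # Torr
    temperature: float = 300.0         # K
    buffer_gas_mass: float = HELIUM_MASS  # u
    voltages: tuple[float, ...] = (25.0, 32.0, 39.0, 46.0, 53.0, 60.0)
    dead_time_coeff: float = 2.0       # us per sqrt(m/z)
    width_inflation: float = 2.0       # dimensionless, >= 1
    bin_width: float = 5.0             # us

    def __post_init__(self):
        if self.pressure <= 0 or self.temperature <= 0 or self.drift_length <= 0:
            raise ValueError("pressure, temperature and drift length must be positive")
        if len(self.voltages) < 2:
            raise ValueError("need at least 2 drift voltages")
        if any(v <= 0 for v in self.voltages):
            raise ValueError("drift voltages must be positive")
        if len(set(self.voltages)) != len(self.voltages):
            raise ValueError("drift voltages must be distinct")
        if self.width_inflation < 1:
            raise ValueError("width_inflation must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Counting-statistics model: expected counts at the tallest peak
    (0 = noise-free exact profile) plus a flat mean baseline per bin."""

    peak_counts: float = 0.0
    baseline_counts: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.peak_counts < 0 or self.baseline_counts < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground-truth conformer family: CCS in Angstrom^2 and its relative
    abundance within the species."""

    ccs: float
    abundance: float


@dataclass(frozen=True)
class GroundTruth:
    """Labelled truth for one simulated species: 1-4 conformer families
    with abundances summing to 1."""

    species: IonSpecies
    families: tuple[FamilyTruth, ...]
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        if not 1 <= len(self.families) <= 4:
            raise ValueError("need 1-4 conformer families per species")
        if any(f.abundance < 0 for f in self.families):
            raise ValueError("abundances must be non-negative")
        total = sum(f.abundance for f in self.families)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")
        if any(f.ccs <= 0 for f in self.families):
            raise ValueError("CCS values must be positive")
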