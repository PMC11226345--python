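"""Arrival-time-distribution containers shared by the generator and the
deconvolution stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .instrument import InstrumentConfig

__all__ = ["ATDTrace", "ATDSet"]


@dataclass(frozen=True)
class ATDTrace:
    """One arrival-time trace at a single drift voltage."""

    pressure: float            # Torr
    voltage: float             # V
    times: np.ndarray          # ms, bin centres, strictly increasing
    intensities: np.ndarray    # counts (or exact profile when noise-free)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.intensities) != len(t):
            raise ValueError("times and intensities must have equal length")


@dataclass
class ATDSet:
    """Arrival-time traces of one m/z-selected species across drift voltages."""

    traces: list[ATDTrace]
    mz: float
    meta: InstrumentConfig
    manifest: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.traces) < 2:
            raise ValueError("an ATD set needs traces at >= 2 drift voltages")
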