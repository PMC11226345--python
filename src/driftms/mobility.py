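"""Drift-tube mobility physics: arrival-time regression, reduced-mobility
normalisation, and the Mason-Schamp conversion between mobility and
collision cross section.

An ion pulsed into a drift cell of length ``L`` at pressure ``P`` and
temperature ``T`` under a drift voltage ``V`` arrives after

    t_arrival = t_dead(m/z) + L^2 / (K * V)

where ``K`` is the ion mobility at cell conditions.  Measuring arrival
times at several voltages and regressing ``t`` on ``P/V`` separates the
voltage-invariant dead time (intercept) from the mobility (slope).  The
reduced mobility ``K0`` (normalised to 273.15 K and 760 Torr) is converted
to the momentum-transfer collision cross section via the Mason-Schamp
equation

    Omega = (3 z e) / (16 N0) * sqrt(2 pi / (mu kb T)) * 1 / K0

with ``mu`` the ion/buffer-gas reduced mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np

from .constants import CODATA

if TYPE_CHECKING:  # pragma: no cover
    from .instrument import InstrumentConfig

__all__ = [
    "MobilityFit",
    "reduced_mass",
    "ccs_from_reduced_mobility",
    "K0_from_ccs",
    "normalize_mobility",
    "dead_time_ms",
    "predict_arrival_time",
    "mobility_regression",
]


@dataclass(frozen=True)
class MobilityFit:
    """Result of the arrival-time vs P/V regression.

    slope is in ms per (Torr/V), intercept (the dead time) in ms, K0 in
    cm^2 V^-1 s^-1.
    """

    slope: float
    intercept: float
    r_squared: float
    K0: float
    K0_stderr: float
    n_points: int


def reduced_mass(ion_mass: float, gas_mass: float) -> float:
    """Reduced mass ``m1*m2/(m1+m2)`` of the ion/buffer-gas pair, in u."""
    if ion_mass <= 0 or gas_mass <= 0:
        raise ValueError("masses must be positive")
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def _mason_schamp_prefactor(z: int, T: float, mu: float) -> float:
    """(3ze/16N0) sqrt(2pi/(mu kb T)) with mu in u; result in m^2 per (m^2/Vs)."""
    mu_kg = mu * CODATA.amu_to_kg
    return (3.0 * z * CODATA.e / (16.0 * CODATA.N0)) * math.sqrt(
        2.0 * math.pi / (mu_kg * CODATA.kb * T)
    )


def ccs_from_reduced_mobility(K0: float, z: int, T: float, mu: float) -> float:
    """Mason-Schamp collision cross section, Angstrom^2.

    Parameters
    ----------
    K0 : reduced mobility, cm^2 V^-1 s^-1
    z : charge count
    T : buffer-gas temperature, K
    mu : reduced mass of ion and buffer gas, u
    """
    if K0 <= 0 or z <= 0 or T <= 0 or mu <= 0:
        raise ValueError("all arguments must be positive")
    K0_si = K0 * 1e-4  # cm^2/Vs -> m^2/Vs
    omega_m2 = _mason_schamp_prefactor(z, T, mu) / K0_si
    return omega_m2 * 1e20  # m^2 -> A^2


def K0_from_ccs(ccs: float, z: int, T: float, mu: float) -> float:
    """Exact algebraic inverse of :func:`ccs_from_reduced_mobility`."""
    if ccs <= 0 or z <= 0 or T <= 0 or mu <= 0:
        raise ValueError("all arguments must be positive")
    omega_m2 = ccs * 1e-20
    K0_si = _mason_schamp_prefactor(z, T, mu) / omega_m2
    return K0_si * 1e4


def normalize_mobility(K: float, P: float, T: float) -> float:
    """Reduce a mobility measured at (P Torr, T K) to standard conditions."""
    if P <= 0 or T <= 0:
        raise ValueError("P and T must be positive")
    return K * (P / CODATA.P_standard_torr) * (CODATA.T_standard_K / T)


def dead_time_ms(dead_time_coeff_us: float, mz: float) -> float:
    """m/z-dependent, voltage-invariant dead time: coeff * sqrt(m/z), in ms."""
    return dead_time_coeff_us * math.sqrt(mz) * 1e-3


def predict_arrival_time(
    K0: float, instrument: "InstrumentConfig", V: float, mz: float
) -> float:
    """Predicted arrival time (ms) at drift voltage V for a species of
    reduced mobility K0 and nominal m/z."""
    if V <= 0:
        raise ValueError("drift voltage must be positive")
    K = K0 / (
        (instrument.pressure / CODATA.P_standard_torr)
        * (CODATA.T_standard_K / instrument.temperature)
    )
    t_drift_s = instrument.drift_length**2 / (K * V)
    return dead_time_ms(instrument.dead_time_coeff, mz) + t_drift_s * 1e3


def _slope_to_K0(slope_ms_per_torr_per_volt: float, instrument) -> float:
    # t_drift[ms] = 1e3 * L^2 * (273.15/760) * (P/V) / (T*K0)
    c = 1e3 * instrument.drift_length**2 * CODATA.T_standard_K / (
        CODATA.P_standard_torr * instrument.temperature
    )
    return c / slope_ms_per_torr_per_volt


def mobility_regression(
    points: Sequence[tuple[float, float, float]], instrument: "InstrumentConfig"
) -> MobilityFit:
    """Ordinary least squares of arrival time on P/V.

    Parameters
    ----------
    points : sequence of (P Torr, V volts, t ms)

    Returns
    -------
    MobilityFit with intercept = dead time (ms) and K0 extracted from the
    slope; the K0 standard error is propagated from the slope standard
    error (first order, K0 proportional to 1/slope).
    """
    pts = list(points)
    x = np.array([p / v for p, v, _ in pts], dtype=float)
    y = np.array([t for _, _, t in pts], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 points with distinct P/V")
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope <= 0:
        raise ValueError("non-physical mobility: fitted slope is not positive")
    slope_stderr = (
        math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else 0.0
    )
    K0 = _slope_to_K0(slope, instrument)
    K0_stderr = K0 * slope_stderr / slope
    return MobilityFit(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        K0=K0,
        K0_stderr=K0_stderr,
        n_points=n,
    )
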