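"""Synthetic drift-tube instrument.

Generates ground-truth-labelled arrival-time distributions, isotope
profile spectra and CID stick spectra so that the whole inference chain
(deconvolution -> P/V regression -> Mason-Schamp) can be exercised and
validated without access to the instrument.

Peak positions follow the same physics the analysis inverts: each
conformer family of reduced mobility K0 (from its ground-truth CCS)
arrives at ``t_dead(m/z) + L^2/(K V)``.  Peak widths follow the
diffusion-limited single-peak resolving power of a low-field drift tube,

    t / dt_FWHM = sqrt(z e V / (16 ln2 kb T)),

inflated by a configurable factor for gate and detector broadening.
Counting noise, when requested, is Poisson per time bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .atd import ATDSet, ATDTrace
from .constants import CODATA
from .instrument import GroundTruth, InstrumentConfig
from .mobility import K0_from_ccs, dead_time_ms, predict_arrival_time, reduced_mass
from .species import IonSpecies, IsotopePattern, isotope_pattern

__all__ = [
    "diffusion_sigma_ms",
    "simulate_atd_set",
    "ProfileSpectrum",
    "simulate_isotope_spectrum",
    "CIDStick",
    "simulate_cid_spectrum",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


def diffusion_sigma_ms(
    t_drift_ms: float, z: int, V: float, instrument: InstrumentConfig
) -> float:
    """Gaussian sigma (ms) of a diffusion-limited drift peak, inflated by
    the instrument's width_inflation factor."""
    resolving = math.sqrt(
        z * CODATA.e * V / (16.0 * math.log(2.0) * CODATA.kb * instrument.temperature)
    )
    return instrument.width_inflation * t_drift_ms / (_FWHM * resolving)


def _gaussian_bin_areas(
    centres: np.ndarray, bin_width: float, mu: float, sigma: float
) -> np.ndarray:
    """Exact integral of a unit-area Gaussian over each bin."""
    lo = (centres - bin_width / 2 - mu) / sigma
    hi = (centres + bin_width / 2 - mu) / sigma
    return ndtr(hi) - ndtr(lo)


def simulate_atd_set(truth: GroundTruth, instrument: InstrumentConfig) -> ATDSet:
    """Simulate one m/z-selected ATD bundle across all drift voltages.

    Each conformer family contributes a Gaussian centred at the predicted
    arrival time with area proportional to its ground-truth abundance.
    With ``noise.peak_counts > 0`` the profile is scaled so its tallest
    bin over all traces has that expectation, a flat baseline is added,
    and every bin is Poisson-drawn; otherwise the exact profile is
    returned.  Ground-truth labels are embedded in the manifest.

    Raises
    ------
    ValueError
        If the time binning is too coarse for the narrowest simulated
        peak (bin_width > sigma/2), or the species list is empty.
    """
    if truth.species is None:
        raise ValueError("ground truth must name a species")
    sp = truth.species
    mu_u = reduced_mass(sp.mass_avg, instrument.buffer_gas_mass)
    bin_ms = instrument.bin_width * 1e-3
    t_dead = dead_time_ms(instrument.dead_time_coeff, sp.mz_avg)

    # (voltage -> [(centre, sigma, area)...]); also the global sigma check
    components: dict[float, list[tuple[float, float, float]]] = {}
    sigma_min = math.inf
    for V in instrument.voltages:
        comps = []
        for fam in truth.families:
            K0 = K0_from_ccs(fam.ccs, sp.z, instrument.temperature, mu_u)
            centre = predict_arrival_time(K0, instrument, V, sp.mz_avg)
            sigma = diffusion_sigma_ms(centre - t_dead, sp.z, V, instrument)
            sigma_min = min(sigma_min, sigma)
            comps.append((centre, sigma, fam.abundance))
        components[V] = comps

    if bin_ms > sigma_min / 2.0:
        raise ValueError(
            "time binning too coarse for the narrowest simulated peak: "
            f"bin_width = {instrument.bin_width:.3g} us exceeds sigma/2 = "
            f"{sigma_min * 500:.3g} us; reduce bin_width or raise width_inflation"
        )

    t_max = max(c + 6 * s for comps in components.values() for c, s, _ in comps)
    n_bins = int(math.ceil(t_max / bin_ms)) + 1
    centres = (np.arange(n_bins) + 0.5) * bin_ms

    exact_traces = []
    for V in instrument.voltages:
        profile = np.zeros(n_bins)
        for centre, sigma, area in components[V]:
            profile += area * _gaussian_bin_areas(centres, bin_ms, centre, sigma)
        exact_traces.append((V, profile))

    noise = truth.noise
    traces = []
    if noise.peak_counts > 0:
        rng = np.random.default_rng(noise.seed)
        peak = max(p.max() for _, p in exact_traces)
        for V, profile in exact_traces:
            lam = profile * (noise.peak_counts / peak) + noise.baseline_counts
            counts = rng.poisson(lam).astype(float)
            traces.append(ATDTrace(instrument.pressure, V, centres.copy(), counts))
    else:
        for V, profile in exact_traces:
            traces.append(ATDTrace(instrument.pressure, V, centres.copy(), profile))

    manifest = {
        "species": sp.label,
        "formula": dict(sp.oligomer_formula),
        "n": sp.n,
        "z": sp.z,
        "mz_avg": sp.mz_avg,
        "ion_mass_avg": sp.mass_avg,
        "families": [
            {"ccs_A2": f.ccs, "abundance": f.abundance} for f in truth.families
        ],
        "instrument": {
            "drift_length_cm": instrument.drift_length,
            "pressure_torr": instrument.pressure,
            "temperature_K": instrument.temperature,
            "buffer_gas_mass_u": instrument.buffer_gas_mass,
            "voltages_V": list(instrument.voltages),
            "dead_time_coeff_us": instrument.dead_time_coeff,
            "width_inflation": instrument.width_inflation,
            "bin_width_us": instrument.bin_width,
        },
        "noise": {
            "peak_counts": noise.peak_counts,
            "baseline_counts": noise.baseline_counts,
            "seed": noise.seed,
        },
    }
    return ATDSet(traces=traces, mz=sp.mz_avg, meta=instrument, manifest=manifest)


@dataclass(frozen=True)
class ProfileSpectrum:
    """Gaussian-broadened profile spectrum on a uniform m/z grid."""

    mz: np.ndarray
    intensity: np.ndarray
    too_coarse: bool = False


def simulate_isotope_spectrum(
    species_weights: list[tuple[IonSpecies, float]],
    resolving_power: float = 50_000.0,
    grid_step: float = 0.002,
    abundance_floor: float = 1e-3,
) -> ProfileSpectrum:
    """Profile spectrum of a weighted species mixture.

    Each species' isotopologue sticks are broadened to Gaussians of
    FWHM = m/z / resolving_power and summed with the given weights; the
    result is normalised to a maximum intensity of 1.  If the grid cannot
    resolve the finest 1/z isotope spacing at the requested resolving
    power the output carries a ``too_coarse`` flag.
    """
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    if not species_weights or all(w == 0 for _, w in species_weights):
        raise ValueError("need at least one species with positive weight")
    if any(w < 0 for _, w in species_weights):
        raise ValueError("weights must be non-negative")

    patterns = [
        (isotope_pattern(sp.oligomer_formula, sp.z, abundance_floor), w)
        for sp, w in species_weights
        if w > 0
    ]
    lo = min(p.mz.min() for p, _ in patterns)
    hi = max(p.mz.max() for p, _ in patterns)
    pad = 5 * hi / resolving_power
    grid = np.arange(lo - pad, hi + pad, grid_step)

    intensity = np.zeros_like(grid)
    for pat, w in patterns:
        for mz, ab in pat.sticks:
            sigma = mz / resolving_power / _FWHM
            intensity += w * ab * np.exp(-0.5 * ((grid - mz) / sigma) ** 2)
    intensity /= intensity.max()

    min_spacing = min(p.spacing for p, _ in patterns)
    too_coarse = grid_step > min_spacing / 4.0
    return ProfileSpectrum(mz=grid, intensity=intensity, too_coarse=too_coarse)


@dataclass(frozen=True)
class CIDStick:
    mz: float
    intensity: float
    fragment: str
    indistinguishable: bool


def simulate_cid_spectrum(
    parent: IonSpecies, channel_weights: dict[tuple[tuple[int, int], tuple[int, int]], float]
) -> list[CIDStick]:
    """Stick spectrum of collision-induced fission fragments.

    ``channel_weights`` maps unordered binary-fission channels
    ((n1, z1), (n2, z2)) to weights; every channel must be a valid
    fission of the parent.  Fragments whose average m/z coincides with
    the parent's (within 0.01) are flagged indistinguishable — in a real
    experiment they hide under the precursor peak.
    """
    from .assign import cid_channels

    valid = {c.key for c in cid_channels(parent)}
    sticks: list[CIDStick] = []
    for channel, w in channel_weights.items():
        key = tuple(sorted(channel))
        if key not in valid:
            raise ValueError(f"channel {channel} is not a valid fission of {parent.label}")
        if w < 0:
            raise ValueError("channel weights must be non-negative")
        for n_f, z_f in key:
            mz = (n_f * parent.monomer_mass_avg + z_f * CODATA.proton_mass) / z_f
            sticks.append(
                CIDStick(
                    mz=mz,
                    intensity=w,
                    fragment=f"[{n_f}M+{z_f}H]{z_f}+",
                    indistinguishable=abs(mz - parent.mz_avg) <= 0.01,
                )
            )
    return sorted(sticks, key=lambda s: s.mz)
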