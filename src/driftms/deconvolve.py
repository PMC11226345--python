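"""Arrival-time-distribution deconvolution.

Multimodal ATDs are resolved into Gaussian components (up to four
conformer families per species), the components are tracked across
drift voltages by arrival-time rank — mobility ordering is preserved at
every voltage because t is proportional to 1/K at fixed V — and each
family's P/V regression yields its reduced mobility, hence its CCS.
Families from all charge states of one oligomer order are finally pooled
into a composite CCS distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, peak_widths
from scipy.special import ndtr

from .atd import ATDSet, ATDTrace
from .instrument import InstrumentConfig
from .mobility import MobilityFit, ccs_from_reduced_mobility, mobility_regression, reduced_mass

__all__ = [
    "PeakComponent",
    "ConformerFamily",
    "CompositeDistribution",
    "deconvolve_atd",
    "deconvolve_set",
    "track_families",
    "family_ccs",
    "composite_distribution",
    "analyse_atd_set",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PeakComponent:
    """One fitted Gaussian: centroid/sigma in ms, area in trace units."""

    centroid: float
    sigma: float
    area: float


@dataclass
class ConformerFamily:
    """One conformer family tracked across drift voltages.

    ``per_voltage_centroids`` holds (V, centroid ms, sigma ms, area);
    rank 1 is the earliest-arriving (most compact) family.  ``ccs`` and
    the mobility fit are filled in by :func:`family_ccs`.
    """

    rank: int
    per_voltage_centroids: list[tuple[float, float, float, float]]
    ccs: float | None = None
    ccs_stderr: float | None = None
    abundance: float | None = None
    fit: MobilityFit | None = None


@dataclass
class CompositeDistribution:
    """Per-oligomer-order weighted Gaussian mixture on the CCS axis."""

    components: dict[int, list[tuple[float, float, float]]]  # n -> (mean, sd, weight)

    def support(self, n: int, n_sigma: float = 2.0) -> tuple[float, float]:
        comps = self.components[n]
        return (
            min(m - n_sigma * s for m, s, _ in comps),
            max(m + n_sigma * s for m, s, _ in comps),
        )


def _mixture_model(params: np.ndarray, t: np.ndarray, bin_w: float) -> np.ndarray:
    """params = [baseline, (area, mu, sigma) * k]; baseline in counts/bin."""
    out = np.full_like(t, params[0])
    for j in range(1, len(params), 3):
        area, mu, sig = params[j : j + 3]
        lo = (t - bin_w / 2 - mu) / sig
        hi = (t + bin_w / 2 - mu) / sig
        out += area * (ndtr(hi) - ndtr(lo))
    return out


def _mixture_jacobian(params: np.ndarray, t: np.ndarray, bin_w: float) -> np.ndarray:
    J = np.empty((len(t), len(params)))
    J[:, 0] = 1.0
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)
    for j in range(1, len(params), 3):
        area, mu, sig = params[j : j + 3]
        lo = (t - bin_w / 2 - mu) / sig
        hi = (t + bin_w / 2 - mu) / sig
        phi_lo = inv_sqrt2pi * np.exp(-0.5 * lo * lo)
        phi_hi = inv_sqrt2pi * np.exp(-0.5 * hi * hi)
        J[:, j] = ndtr(hi) - ndtr(lo)
        J[:, j + 1] = area * (phi_lo - phi_hi) / sig
        J[:, j + 2] = area * (lo * phi_lo - hi * phi_hi) / sig
    return J


def _fit_k_gaussians(
    t: np.ndarray, y: np.ndarray, k: int, seeds: list[tuple[float, float, float]], bin_w: float
) -> tuple[list[PeakComponent], float]:
    """Weighted least-squares fit of a flat baseline plus k bin-integrated
    Gaussians from (centroid, sigma, area) initial guesses.

    Residuals are weighted by 1/sqrt(max(y, 1)) — the Poisson-counting
    approximation — so the returned figure of merit is a chi-square.
    """
    w = 1.0 / np.sqrt(np.clip(y, 1.0, None))
    baseline0 = float(np.median(y))
    x0 = np.concatenate([[baseline0], _flatten(seeds[:k], bin_w)])
    span = t[-1] - t[0]
    lb, ub = [0.0], [max(baseline0 * 4, 1e-12)]
    for _ in range(k):
        lb += [0.0, t[0], bin_w / 4]
        ub += [np.inf, t[-1], span]
    sol = least_squares(
        lambda p: (_mixture_model(p, t, bin_w) - y) * w,
        x0,
        jac=lambda p: _mixture_jacobian(p, t, bin_w) * w[:, None],
        bounds=(lb, ub),
        method="trf",
        x_scale="jac",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    comps = [
        PeakComponent(area=sol.x[j], centroid=sol.x[j + 1], sigma=sol.x[j + 2])
        for j in range(1, 3 * k + 1, 3)
    ]
    chi2 = float(np.sum(sol.fun**2))
    return sorted(comps, key=lambda c: c.centroid), chi2


def _flatten(seeds: list[tuple[float, float, float]], bin_w: float) -> np.ndarray:
    out = []
    for c, s, a in seeds:
        out += [a, c, s]
    return np.array(out)


def _initial_peaks(
    t: np.ndarray, y: np.ndarray, threshold: float, bin_w: float
) -> list[tuple[float, float, float]]:
    baseline = float(np.median(y))
    idx, props = find_peaks(y - baseline, height=threshold, prominence=threshold / 2)
    if len(idx) == 0:
        return []
    w, _, _, _ = peak_widths(y - baseline, idx, rel_height=0.5)
    seeds = []
    for i, width_bins in zip(idx, w):
        sigma = max(width_bins * bin_w / _FWHM, bin_w / 2)
        # intensities are counts per bin, so total area = height * sigma * sqrt(2pi) / bin
        area = (y[i] - baseline) * sigma * math.sqrt(2 * math.pi) / bin_w
        seeds.append((t[i], sigma, area))
    # tallest first; ties broken toward earlier time
    seeds.sort(key=lambda s: (-s[2], s[0]))
    return seeds


def deconvolve_atd(
    trace: ATDTrace,
    k_max: int = 4,
    min_snr: float = 3.0,
    extra_seeds: list[tuple[float, float, float]] | None = None,
) -> list[PeakComponent]:
    """Gaussian-mixture deconvolution of one ATD trace.

    Fits with k = 1..k_max components are compared under the Bayesian
    information criterion chi2 + (3k + 1) ln(n), with residuals weighted
    by the Poisson-counting scale sqrt(max(y, 1)); the smallest k within
    one penalty unit of the minimum is kept.  Centroid seeds come from
    local maxima above ``min_snr`` times the baseline noise scale (median
    absolute deviation); if no local maximum clears the threshold an
    empty list is returned.  ``extra_seeds`` is an optional list of
    (centroid, sigma, area) guesses — e.g. scaled from a better-resolved
    trace — tried as an additional starting point at every k.
    """
    if not 1 <= k_max <= 4:
        raise ValueError("k_max must be in 1..4")
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.intensities, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    bin_w = float(np.median(np.diff(t)))

    mad = float(np.median(np.abs(y - np.median(y))))
    noise_scale = 1.4826 * mad
    threshold = max(min_snr * noise_scale, 1e-9 * float(y.max()))
    seeds = _initial_peaks(t, y, threshold, bin_w)
    if not seeds:
        return []

    total_power = float(np.sum(y**2 / np.clip(y, 1.0, None)))
    fits, chi2s = [], []
    ranked_extra = (
        sorted(extra_seeds, key=lambda s: -s[2]) if extra_seeds else []
    )
    for k in range(1, k_max + 1):
        candidates = []
        if len(seeds) >= k:
            candidates.append(seeds[:k])
        if len(ranked_extra) >= k:
            candidates.append(sorted(ranked_extra[:k], key=lambda s: s[0]))
        if fits:
            # residual peeling: previous fit plus a component at the
            # largest positive residual
            prev = fits[-1]
            prev_params = np.concatenate(
                [[float(np.median(y))], _flatten([(c.centroid, c.sigma, c.area) for c in prev], bin_w)]
            )
            resid = y - _mixture_model(prev_params, t, bin_w)
            i = int(np.argmax(resid))
            sig0 = min(c.sigma for c in prev)
            extra = (
                t[i],
                sig0,
                max(resid[i], 1e-12 * y.max()) * sig0 * math.sqrt(2 * math.pi) / bin_w,
            )
            candidates.append(
                [(c.centroid, c.sigma, c.area) for c in prev] + [extra]
            )
        best = None
        for cand in candidates:
            comps, r = _fit_k_gaussians(t, y, k, cand, bin_w)
            if best is None or r < best[1]:
                best = (comps, r)
        fits.append(best[0])
        chi2s.append(best[1])
        if best[1] <= 1e-16 * total_power:  # numerically exact
            return fits[-1]
    penalty = math.log(len(t))
    bic = [c + (3 * k + 1) * penalty for k, c in enumerate(chi2s, start=1)]
    best_bic = min(bic)
    for k, b in enumerate(bic, start=1):
        # smallest k statistically indistinguishable from the optimum
        if b <= best_bic + penalty:
            return fits[k - 1]
    return fits[-1]


def deconvolve_set(
    atd: ATDSet, k_max: int = 4, min_snr: float = 3.0
) -> dict[float, list[PeakComponent]]:
    """Deconvolve every trace; returns voltage -> components.

    Traces are processed from the highest drift voltage (best peak
    separation in units of the diffusion width) downwards; each fit
    seeds the next trace with its components scaled by the voltage
    ratio, since drift time is proportional to 1/V and the diffusion
    width grows as V^(-3/2).  This keeps strongly overlapping
    low-voltage mixtures on the same solution branch.
    """
    ordered = sorted(atd.traces, key=lambda tr: -tr.voltage)
    out: dict[float, list[PeakComponent]] = {}
    prev: tuple[float, list[PeakComponent]] | None = None
    for tr in ordered:
        extra = None
        if prev is not None and prev[1]:
            v_prev, comps = prev
            scale = v_prev / tr.voltage
            extra = [
                (c.centroid * scale, c.sigma * scale**1.5, c.area) for c in comps
            ]
        comps = deconvolve_atd(tr, k_max, min_snr, extra_seeds=extra)
        out[tr.voltage] = comps
        if comps:
            prev = (tr.voltage, comps)
    return {tr.voltage: out[tr.voltage] for tr in atd.traces}


def track_families(
    per_voltage_components: dict[float, list[PeakComponent]],
) -> list[ConformerFamily]:
    """Match components across voltages by arrival-time rank.

    Rank k at each voltage joins family k (mobility ordering is
    voltage-invariant).  A family missing a component at some voltage
    keeps its remaining points if at least two survive, and is dropped
    with a warning otherwise.
    """
    voltages = sorted(per_voltage_components)
    if len(voltages) < 2:
        raise ValueError("need components at >= 2 voltages")
    counts = [len(per_voltage_components[v]) for v in voltages]
    if max(counts) == 0:
        raise ValueError("no components at any voltage")
    if any(abs(a - b) > 1 for a, b in zip(counts, counts[1:])):
        warnings.warn(
            "component counts differ by >1 across adjacent voltages; "
            "rank matching may mispair families",
            stacklevel=2,
        )
    families = []
    for rank in range(1, max(counts) + 1):
        pts = []
        for v in voltages:
            comps = sorted(per_voltage_components[v], key=lambda c: c.centroid)
            if len(comps) >= rank:
                c = comps[rank - 1]
                pts.append((v, c.centroid, c.sigma, c.area))
        if len(pts) >= 2:
            families.append(ConformerFamily(rank=rank, per_voltage_centroids=pts))
        else:
            warnings.warn(
                f"family rank {rank} observed at <2 voltages; dropped", stacklevel=2
            )
    return families


def family_ccs(
    family: ConformerFamily,
    z: int,
    ion_mass: float,
    instrument: InstrumentConfig,
    per_voltage_totals: dict[float, float] | None = None,
) -> ConformerFamily:
    """Complete a family: P/V regression, Mason-Schamp CCS, abundance.

    ``per_voltage_totals`` maps voltage to the summed area of all
    components in that trace; the family abundance is its mean fractional
    area across voltages (1.0 if totals are not supplied).
    """
    if len(family.per_voltage_centroids) < 2:
        raise ValueError("family needs >= 2 voltage points")
    pts = [(instrument.pressure, v, t) for v, t, _, _ in family.per_voltage_centroids]
    fit = mobility_regression(pts, instrument)
    mu = reduced_mass(ion_mass, instrument.buffer_gas_mass)
    ccs = ccs_from_reduced_mobility(fit.K0, z, instrument.temperature, mu)
    ccs_stderr = ccs * fit.K0_stderr / fit.K0 if fit.K0 else 0.0
    if per_voltage_totals:
        fracs = [
            area / per_voltage_totals[v]
            for v, _, _, area in family.per_voltage_centroids
            if per_voltage_totals.get(v)
        ]
        abundance = float(np.mean(fracs)) if fracs else 0.0
    else:
        abundance = 1.0
    family.ccs = ccs
    family.ccs_stderr = ccs_stderr
    family.abundance = abundance
    family.fit = fit
    return family


def analyse_atd_set(
    atd: ATDSet, z: int, ion_mass: float, k_max: int = 4, min_snr: float = 3.0
) -> list[ConformerFamily]:
    """Full per-species chain: deconvolve each trace, track families by
    rank, regress each family and convert to CCS."""
    per_v = deconvolve_set(atd, k_max, min_snr)
    totals = {v: sum(c.area for c in comps) for v, comps in per_v.items()}
    families = track_families(per_v)
    return [family_ccs(f, z, ion_mass, atd.meta, totals) for f in families]


def composite_distribution(
    assignments: list[tuple[int, ConformerFamily]],
) -> CompositeDistribution:
    """Pool families from all charge states into per-oligomer-order CCS
    mixtures; each family becomes a Gaussian at its CCS with width
    max(ccs_stderr, 1% of CCS), weights renormalised within the order."""
    if not assignments:
        raise ValueError("need at least one family")
    by_n: dict[int, list[tuple[float, float, float]]] = {}
    for n, fam in assignments:
        if fam.ccs is None:
            raise ValueError("family has no CCS; run family_ccs first")
        sd = max(fam.ccs_stderr or 0.0, 0.01 * fam.ccs)
        by_n.setdefault(n, []).append((fam.ccs, sd, fam.abundance or 0.0))
    out = {}
    for n, comps in by_n.items():
        total = sum(w for _, _, w in comps)
        if total <= 0:
            w_norm = [(m, s, 1.0 / len(comps)) for m, s, _ in comps]
        else:
            w_norm = [(m, s, w / total) for m, s, w in comps]
        out[n] = w_norm
    return CompositeDistribution(components=out)
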