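"""Ion species bookkeeping and isotope-pattern simulation.

Protein oligomers observed by native electrospray take the form
[nM + zH]^z+.  Because the average m/z of [knM + kzH]^kz+ is identical to
that of [nM + zH]^z+ for every integer k, nominal peak assignments are
degenerate ("aggromers"); only the isotopologue spacing (1.00336/z) or
dissociation behaviour breaks the degeneracy.  This module builds exact
elemental formulas from chain sequences, simulates isotopologue
distributions by iterated convolution of elemental isotope vectors, and
enumerates the m/z-coincident candidate set for an observed peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
from pyteomics import mass as pmass

from .constants import CODATA, NEUTRON_SPACING

__all__ = [
    "IonSpecies",
    "IsotopePattern",
    "elemental_formula",
    "isotope_pattern",
    "coincident_candidates",
    "insulin_chains",
    "insulin_species",
]

# IUPAC 2021 isotopic compositions for the elements occurring in proteins.
# Each entry: list of (mass u, fractional abundance), lightest first.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [
        (15.9949146221, 0.99757),
        (16.9991315, 0.00038),
        (17.9991604, 0.00205),
    ],
    "S": [
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ],
}


@dataclass(frozen=True)
class IonSpecies:
    """An [nM + zH]^z+ oligomer ion of a single monomer sequence."""

    label: str
    n: int
    z: int
    formula: Mapping[str, int]
    monomer_mass_avg: float
    monomer_mass_mono: float

    def __post_init__(self):
        if self.n < 1 or self.z < 1:
            raise ValueError("oligomer order and charge must be >= 1")

    @property
    def mass_avg(self) -> float:
        return self.n * self.monomer_mass_avg

    @property
    def mass_mono(self) -> float:
        return self.n * self.monomer_mass_mono

    @property
    def mz_avg(self) -> float:
        return (self.mass_avg + self.z * CODATA.proton_mass) / self.z

    @property
    def mz_mono(self) -> float:
        return (self.mass_mono + self.z * CODATA.proton_mass) / self.z

    @property
    def oligomer_formula(self) -> dict[str, int]:
        return {el: self.n * c for el, c in self.formula.items()}


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue stick pattern of a single charged species.

    Sticks are equally spaced by ``NEUTRON_SPACING / z`` starting at the
    monoisotopic m/z; abundances are normalised to a maximum of 1.
    """

    sticks: tuple[tuple[float, float], ...]
    charge: int

    @property
    def spacing(self) -> float:
        return NEUTRON_SPACING / self.charge

    @property
    def mz(self) -> np.ndarray:
        return np.array([s[0] for s in self.sticks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([s[1] for s in self.sticks])


def elemental_formula(
    sequence_chains: Iterable[str], disulfides: int, n: int = 1
) -> dict[str, int]:
    """Elemental formula of an n-mer of a (possibly multi-chain) monomer.

    Each chain contributes its residue formulas plus one H2O; each
    disulfide bond removes 2 H.  The whole monomer formula is then
    multiplied by the oligomer order ``n``.
    """
    if n < 1:
        raise ValueError("oligomer order must be >= 1")
    total = pmass.Composition()
    n_cys = 0
    for chain in sequence_chains:
        chain = chain.strip().upper()
        for aa in chain:
            if aa not in pmass.std_aa_comp:
                raise ValueError(f"unknown residue {aa!r}")
        total += pmass.Composition(sequence=chain)  # includes H2O termini
        n_cys += chain.count("C")
    if disulfides > n_cys // 2:
        raise ValueError("more disulfides than available cysteine pairs")
    total["H"] -= 2 * disulfides
    return {el: n * cnt for el, cnt in sorted(total.items()) if cnt}


def _convolve_pruned(p: np.ndarray, q: np.ndarray, floor: float = 1e-15) -> np.ndarray:
    r = np.convolve(p, q)
    r[r < floor * r.max()] = 0.0
    # trim trailing zeros to keep vectors short
    nz = np.nonzero(r)[0]
    return r[: nz[-1] + 1] if len(nz) else r[:1]

def _element_neutron_vector(el: str) -> np.ndarray:
    """Abundance vector of one atom indexed by added-neutron count."""
    isos = ISOTOPES[el]
    base = round(isos[0][0])
    size = round(isos[-1][0]) - base + 1
    v = np.zeros(size)
    for m, a in isos:
        v[round(m) - base] += a
    return v


def _power_convolve(v: np.ndarray, count: int) -> np.ndarray:
    """v convolved with itself ``count`` times (binary exponentiation)."""
    result = np.array([1.0])
    base = v
    while count:
        if count & 1:
            result = _convolve_pruned(result, base)
        base = _convolve_pruned(base, base)
        count >>= 1
    return result


@lru_cache(maxsize=64)
def _aggregate_distribution(formula_items: tuple[tuple[str, int], ...]) -> np.ndarray:
    dist = np.array([1.0])
    for el, cnt in formula_items:
        if cnt == 0:
            continue
        dist = _convolve_pruned(dist, _power_convolve(_element_neutron_vector(el), cnt))
    return dist


def isotope_pattern(
    formula: Mapping[str, int], z: int, abundance_floor: float = 1e-3
) -> IsotopePattern:
    """Aggregated isotopologue distribution of a formula at charge z.

    The distribution over added-neutron number is computed by iterated
    convolution of the elemental isotope vectors; sticks are placed at
    (monoisotopic mass + k * 1.00336 u + z protons)/z and pruned below
    ``abundance_floor`` of the maximum.  Pruning never removes the most
    abundant stick.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    items = tuple(sorted((el, c) for el, c in formula.items() if c))
    if not items:
        raise ValueError("empty formula")
    dist = _aggregate_distribution(items)
    mono = sum(ISOTOPES[el][0][0] * c for el, c in items)
    dist = dist / dist.max()
    sticks = [
        ((mono + k * NEUTRON_SPACING + z * CODATA.proton_mass) / z, a)
        for k, a in enumerate(dist)
        if a >= abundance_floor
    ]
    return IsotopePattern(sticks=tuple(sticks), charge=z)


def coincident_candidates(
    mz_obs: float,
    monomer_formula: Mapping[str, int],
    tol: float = 0.5,
    n_max: int = 12,
    z_max: int = 40,
) -> list[IonSpecies]:
    """All [nM + zH]^z+ whose average m/z lies within tol of an observed peak.

    Because mz_avg(kn, kz) == mz_avg(n, z), a nominal monomer peak always
    admits the whole aggromer ladder; the list is sorted by oligomer order.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    m_avg = pmass.calculate_mass(
        composition=pmass.Composition(monomer_formula), average=True
    )
    m_mono = pmass.calculate_mass(composition=pmass.Composition(monomer_formula))
    out = []
    for n in range(1, n_max + 1):
        for z in range(1, z_max + 1):
            mz = (n * m_avg + z * CODATA.proton_mass) / z
            if abs(mz - mz_obs) <= tol:
                out.append(
                    IonSpecies(
                        label=f"[{n}M+{z}H]{z}+",
                        n=n,
                        z=z,
                        formula=dict(monomer_formula),
                        monomer_mass_avg=m_avg,
                        monomer_mass_mono=m_mono,
                    )
                )
    return sorted(out, key=lambda s: (s.n, s.z))


def insulin_chains() -> list[str]:
    """Bovine insulin chain A and B sequences from the packaged FASTA."""
    from Bio import SeqIO

    path = resources.files("driftms.data") / "insulin.fasta"
    with path.open() as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fasta")]


def insulin_species(n: int, z: int) -> IonSpecies:
    """Convenience constructor for bovine insulin [nM + zH]^z+ (3 disulfides)."""
    formula = elemental_formula(insulin_chains(), disulfides=3, n=1)
    comp = pmass.Composition(formula)
    return IonSpecies(
        label=f"[{n}M+{z}H]{z}+",
        n=n,
        z=z,
        formula=formula,
        monomer_mass_avg=pmass.calculate_mass(composition=comp, average=True),
        monomer_mass_mono=pmass.calculate_mass(composition=comp),
    )
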