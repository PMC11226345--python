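"""Species assignment: breaking the aggromer degeneracy.

A peak at nominal m/z admits the whole ladder [knM + kzH]^kz+ of
average-m/z-coincident species.  Two evidence streams resolve it:

* isotope fine structure — the stick spacing is 1.00336/z, so a dimer at
  doubled charge interleaves sticks at half the monomer spacing; a
  non-negative least-squares decomposition of the observed profile onto
  candidate template profiles yields mixture weights;
* collision-induced dissociation — a non-covalent multimer fissions into
  sub-oligomers that partition mass and charge exactly, so observed
  fragments can require a higher-order parent.

`classify_peak` combines both streams into a verdict: multiple ATD peaks
are conformers of one species, or an aggromer mixture (in which case the
earlier-arriving ATD peak belongs to the higher-charge species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import nnls

from .constants import CODATA
from .species import IonSpecies, isotope_pattern
from .simulate import ProfileSpectrum, _FWHM

__all__ = [
    "CIDChannel",
    "cid_channels",
    "decompose_pattern",
    "Verdict",
    "AssignmentVerdict",
    "classify_peak",
]


@dataclass(frozen=True)
class CIDChannel:
    """Unordered binary fission {(n1, z1), (n2, z2)} of a multimer parent."""

    fragments: tuple[tuple[int, int], tuple[int, int]]
    fragment_mz: tuple[float, float]
    parent_indistinguishable: bool

    @property
    def key(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.fragments


def cid_channels(parent: IonSpecies) -> list[CIDChannel]:
    """All binary fission channels of a parent [nM + zH]^z+.

    Fragments satisfy n1 + n2 = n and z1 + z2 = z with all counts >= 1;
    a monomer parent has no channels.  Channels with a fragment whose
    average m/z equals the parent's (within 0.01) are flagged as
    parent-indistinguishable.
    """
    out = []
    seen = set()
    for n1 in range(1, parent.n // 2 + 1):
        n2 = parent.n - n1
        for z1 in range(1, parent.z):
            z2 = parent.z - z1
            key = tuple(sorted(((n1, z1), (n2, z2))))
            if key in seen:
                continue
            seen.add(key)
            mzs = tuple(
                (nf * parent.monomer_mass_avg + zf * CODATA.proton_mass) / zf
                for nf, zf in key
            )
            out.append(
                CIDChannel(
                    fragments=key,
                    fragment_mz=mzs,
                    parent_indistinguishable=any(
                        abs(mz - parent.mz_avg) <= 0.01 for mz in mzs
                    ),
                )
            )
    return sorted(out, key=lambda c: c.fragments)


def _template_profile(
    sp: IonSpecies, grid: np.ndarray, resolving_power: float
) -> np.ndarray:
    pat = isotope_pattern(sp.oligomer_formula, sp.z)
    prof = np.zeros_like(grid)
    for mz, ab in pat.sticks:
        sigma = mz / resolving_power / _FWHM
        prof += ab * np.exp(-0.5 * ((grid - mz) / sigma) ** 2)
    return prof


def decompose_pattern(
    observed: ProfileSpectrum,
    candidates: list[IonSpecies],
    resolving_power: float = 50_000.0,
) -> tuple[dict[str, float], float]:
    """Non-negative least-squares mixture weights of candidate species.

    Template profiles are the candidates' isotope patterns broadened to
    the stated resolving power on the observed grid.  Returns weights
    normalised to sum 1 (keyed by species label) and the relative
    residual norm of the fit.
    """
    if not candidates:
        raise ValueError("need at least one candidate species")
    grid = np.asarray(observed.mz, dtype=float)
    y = np.asarray(observed.intensity, dtype=float)
    if grid.size == 0:
        raise ValueError("observed spectrum is empty")
    templates = np.column_stack(
        [_template_profile(sp, grid, resolving_power) for sp in candidates]
    )
    # identical templates make the problem rank-deficient
    if len(candidates) > 1:
        norms = np.linalg.norm(templates, axis=0)
        unit = templates / norms
        gram = unit.T @ unit
        iu = np.triu_indices(len(candidates), k=1)
        if np.any(gram[iu] > 1.0 - 1e-12):
            raise ValueError("candidate templates are indistinguishable (rank deficient)")
    coef, rnorm = nnls(templates, y)
    total = coef.sum()
    if total == 0:
        weights = {sp.label: 0.0 for sp in candidates}
    else:
        weights = {sp.label: c / total for sp, c in zip(candidates, coef)}
    rel_resid = rnorm / np.linalg.norm(y) if np.linalg.norm(y) else 0.0
    return weights, rel_resid


class Verdict(str, Enum):
    CONFORMERS = "conformers"
    AGGROMER_MIXTURE = "aggromer_mixture"
    UNDETERMINED = "undetermined"


@dataclass
class AssignmentVerdict:
    peak_id: str
    verdict: Verdict
    weights: dict[str, float] = field(default_factory=dict)
    evidence: dict[str, object] = field(default_factory=dict)
    early_peak_species: str | None = None


def _fragment_requires_higher_order(
    nominal: IonSpecies, fragments: list[tuple[int, int]]
) -> bool:
    """True if an observed fragment set cannot come from the nominal parent.

    Any fragment at all from a nominal monomer requires a multimer parent;
    for a multimer, a fragment with n >= parent n is impossible.
    """
    if not fragments:
        return False
    if nominal.n == 1:
        return True
    return any(nf >= nominal.n for nf, _ in fragments)


def classify_peak(
    nominal: IonSpecies,
    atd_family_count: int | None = None,
    pattern_weights: dict[str, float] | None = None,
    cid_fragments_observed: list[tuple[int, int]] | None = None,
    aggromer_threshold: float = 0.05,
) -> AssignmentVerdict:
    """Decide conformers vs aggromer mixture for a multimodal ATD peak.

    Rule: if the isotope decomposition assigns a secondary species a
    weight >= ``aggromer_threshold``, or observed CID fragments require a
    higher-order parent, the peak is an aggromer mixture and the
    earlier-arriving ATD component is assigned to the higher-charge
    (higher-order) species, which drifts faster.  If neither stream shows
    aggromer evidence but at least one is present, the multimodal ATD
    reflects distinct conformers of one species.  With no evidence, or
    with contradictory streams, the verdict is undetermined.
    """
    has_pattern = bool(pattern_weights)
    has_cid = cid_fragments_observed is not None
    if not has_pattern and not has_cid:
        return AssignmentVerdict(peak_id=nominal.label, verdict=Verdict.UNDETERMINED)

    pattern_says_mixture = False
    secondary = None
    if has_pattern:
        others = {
            lab: w for lab, w in pattern_weights.items() if lab != nominal.label
        }
        if others:
            secondary = max(others, key=others.get)
            pattern_says_mixture = others[secondary] >= aggromer_threshold

    cid_says_mixture = has_cid and _fragment_requires_higher_order(
        nominal, cid_fragments_observed or []
    )

    evidence = {
        "pattern_weights": dict(pattern_weights or {}),
        "cid_fragments": list(cid_fragments_observed or []),
        "pattern_says_mixture": pattern_says_mixture,
        "cid_says_mixture": cid_says_mixture,
        "atd_family_count": atd_family_count,
    }

    if has_pattern and has_cid and cid_says_mixture and not pattern_says_mixture:
        # CID demands a higher-order parent the isotope pattern excludes
        return AssignmentVerdict(
            peak_id=nominal.label, verdict=Verdict.UNDETERMINED, evidence=evidence
        )

    if pattern_says_mixture or cid_says_mixture:
        return AssignmentVerdict(
            peak_id=nominal.label,
            verdict=Verdict.AGGROMER_MIXTURE,
            weights=dict(pattern_weights or {}),
            evidence=evidence,
            early_peak_species=secondary,
        )

    weights = dict(pattern_weights) if has_pattern else {nominal.label: 1.0}
    return AssignmentVerdict(
        peak_id=nominal.label,
        verdict=Verdict.CONFORMERS,
        weights=weights,
        evidence=evidence,
    )
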