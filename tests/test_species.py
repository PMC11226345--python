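"""Elemental formulas, isotopologue patterns, aggromer degeneracy and the
evidence streams (isotope decomposition, CID channels) that break it."""

import itertools

import numpy as np
import pytest

import driftms as d
from driftms.assign import classify_peak, decompose_pattern
from driftms.simulate import simulate_isotope_spectrum
from driftms.species import ISOTOPES, _aggregate_distribution


class TestElementalFormula:
    def test_insulin_monomer_formula(self, insulin_monomer_formula):
        assert insulin_monomer_formula == {
            "C": 254, "H": 377, "N": 65, "O": 75, "S": 6
        }

    def test_insulin_average_mass(self):
        sp = d.insulin_species(1, 1)
        assert sp.monomer_mass_avg == pytest.approx(5733.5, abs=0.2)

    def test_each_disulfide_removes_two_hydrogens(self):
        chains = d.insulin_chains()
        h0 = d.elemental_formula(chains, disulfides=0)["H"]
        h3 = d.elemental_formula(chains, disulfides=3)["H"]
        assert h0 - h3 == 6

    def test_dimer_formula_doubles(self, insulin_monomer_formula):
        dim = d.elemental_formula(d.insulin_chains(), disulfides=3, n=2)
        assert dim == {el: 2 * c for el, c in insulin_monomer_formula.items()}

    def test_rejects_unknown_residue(self):
        with pytest.raises(ValueError, match="unknown residue"):
            d.elemental_formula(["ACDX"], disulfides=0)

    def test_rejects_excess_disulfides(self):
        with pytest.raises(ValueError):
            d.elemental_formula(["ACCA"], disulfides=2)


class TestIonSpecies:
    def test_dimer_seven_plus_mz(self, dimer_7plus):
        assert round(dimer_7plus.mz_avg) == 1639

    def test_dimer_four_plus_mz(self):
        assert round(d.insulin_species(2, 4).mz_avg) == 2868

    def test_aggromer_mz_degeneracy_exact(self):
        # average m/z of [2M+6H]6+ equals that of [M+3H]3+ identically
        mono = d.insulin_species(1, 3)
        dim = d.insulin_species(2, 6)
        assert dim.mz_avg == pytest.approx(mono.mz_avg, rel=1e-12)

    def test_rejects_zero_charge(self):
        with pytest.raises(ValueError):
            d.insulin_species(1, 0)


class TestIsotopePattern:
    def test_matches_exhaustive_isotopologue_oracle(self):
        # small formula: exhaustively enumerate isotopic compositions per
        # element (multinomial probabilities) and pool by added-neutron
        # count — independent of the convolution implementation
        import math
        from itertools import product

        formula = {"C": 5, "H": 10, "N": 2, "O": 3, "S": 2}

        def multinomial(counts):
            total = math.factorial(sum(counts))
            for c in counts:
                total //= math.factorial(c)
            return total

        def compositions(total, bins):
            if bins == 1:
                yield (total,)
                return
            for first in range(total + 1):
                for rest in compositions(total - first, bins - 1):
                    yield (first,) + rest

        def element_dist(el, count):
            isos = ISOTOPES[el]
            base = round(isos[0][0])
            out: dict[int, float] = {}
            for split in compositions(count, len(isos)):
                p = multinomial(split)
                k = 0
                for c, (m, a) in zip(split, isos):
                    p *= a**c
                    k += (round(m) - base) * c
                out[k] = out.get(k, 0.0) + p
            return out

        oracle = {0: 1.0}
        for el, cnt in formula.items():
            nxt: dict[int, float] = {}
            for k1, p1 in oracle.items():
                for k2, p2 in element_dist(el, cnt).items():
                    nxt[k1 + k2] = nxt.get(k1 + k2, 0.0) + p1 * p2
            oracle = nxt

        dist = _aggregate_distribution(tuple(sorted(formula.items())))
        for k, p in oracle.items():
            if p > 1e-10:
                assert dist[k] == pytest.approx(p, rel=1e-6)

    def test_most_abundant_stick_not_monoisotopic(self, insulin_monomer_formula):
        # at ~5.7 kDa the aggregate distribution peaks a few neutrons up
        pat = d.isotope_pattern(insulin_monomer_formula, 3)
        i_max = int(np.argmax(pat.abundance))
        assert i_max >= 2
        assert pat.abundance[i_max] == 1.0

    def test_first_stick_is_monoisotopic_mz(self, dimer_7plus):
        # independent isotope mass tables (embedded vs pyteomics) agree
        # to well under the stick spacing
        pat = d.isotope_pattern(dimer_7plus.oligomer_formula, 7, abundance_floor=0.0)
        assert pat.sticks[0][0] == pytest.approx(dimer_7plus.mz_mono, abs=1e-5)

    def test_pruning_keeps_maximum(self, insulin_monomer_formula):
        loose = d.isotope_pattern(insulin_monomer_formula, 3, abundance_floor=1e-9)
        tight = d.isotope_pattern(insulin_monomer_formula, 3, abundance_floor=0.5)
        assert max(loose.abundance) == max(tight.abundance) == 1.0
        assert len(tight.sticks) < len(loose.sticks)

    def test_spacing_is_neutron_over_charge(self, insulin_monomer_formula):
        for z in (1, 3, 7):
            pat = d.isotope_pattern(insulin_monomer_formula, z)
            assert pat.spacing == pytest.approx(1.0033548378 / z, rel=1e-12)
            diffs = np.diff(pat.mz)
            assert diffs == pytest.approx(pat.spacing, rel=1e-9)

    def test_rejects_empty_formula(self):
        with pytest.raises(ValueError):
            d.isotope_pattern({}, 1)


class TestCoincidentCandidates:
    def test_aggromer_ladder_at_monomer_triple_charge(self, insulin_monomer_formula):
        mz = d.insulin_species(1, 3).mz_avg
        cands = d.coincident_candidates(
            mz, insulin_monomer_formula, tol=0.5, n_max=4, z_max=12
        )
        assert [(c.n, c.z) for c in cands] == [(1, 3), (2, 6), (3, 9), (4, 12)]

    def test_off_ladder_mz_matches_nothing(self, insulin_monomer_formula):
        cands = d.coincident_candidates(
            500.0, insulin_monomer_formula, tol=0.1, n_max=4, z_max=12
        )
        assert cands == []

    def test_rejects_nonpositive_tolerance(self, insulin_monomer_formula):
        with pytest.raises(ValueError):
            d.coincident_candidates(1000.0, insulin_monomer_formula, tol=0.0)


class TestDecomposePattern:
    def test_pure_species_recovered(self):
        mono = d.insulin_species(1, 3)
        dim = d.insulin_species(2, 6)
        spec = simulate_isotope_spectrum([(dim, 1.0)], 50_000.0)
        weights, resid = decompose_pattern(spec, [mono, dim])
        assert weights[dim.label] > 0.97
        assert resid < 0.05

    def test_two_species_mixture_weights(self):
        mono = d.insulin_species(1, 3)
        dim = d.insulin_species(2, 6)
        spec = simulate_isotope_spectrum([(mono, 0.7), (dim, 0.3)], 50_000.0)
        weights, _ = decompose_pattern(spec, [mono, dim])
        assert weights[mono.label] == pytest.approx(0.7, abs=0.03)
        assert weights[dim.label] == pytest.approx(0.3, abs=0.03)

    def test_hundred_random_mixtures(self):
        mono = d.insulin_species(1, 3)
        dim = d.insulin_species(2, 6)
        rng = np.random.default_rng(7)
        for w in rng.uniform(0.05, 0.95, size=100):
            spec = simulate_isotope_spectrum([(mono, w), (dim, 1 - w)], 50_000.0)
            weights, _ = decompose_pattern(spec, [mono, dim])
            assert weights[mono.label] == pytest.approx(w, abs=0.03)

    def test_identical_templates_rejected(self):
        sp = d.insulin_species(1, 3)
        spec = simulate_isotope_spectrum([(sp, 1.0)], 50_000.0)
        with pytest.raises(ValueError, match="rank deficient"):
            decompose_pattern(spec, [sp, sp])

    def test_empty_candidates_rejected(self):
        sp = d.insulin_species(1, 3)
        spec = simulate_isotope_spectrum([(sp, 1.0)], 50_000.0)
        with pytest.raises(ValueError):
            decompose_pattern(spec, [])


class TestCIDChannels:
    @staticmethod
    def _oracle(n, z):
        out = set()
        for n1, z1 in itertools.product(range(1, n), range(1, z)):
            out.add(tuple(sorted(((n1, z1), (n - n1, z - z1)))))
        return out

    def test_matches_brute_force_enumeration(self):
        for n, z in itertools.product(range(1, 7), range(1, 16)):
            parent = d.insulin_species(n, z)
            got = {ch.fragments for ch in d.cid_channels(parent)}
            assert got == self._oracle(n, z)

    def test_channels_conserve_mass_and_charge(self):
        parent = d.insulin_species(3, 8)
        for ch in d.cid_channels(parent):
            (n1, z1), (n2, z2) = ch.fragments
            assert n1 + n2 == parent.n
            assert z1 + z2 == parent.z
            assert min(n1, n2, z1, z2) >= 1

    def test_monomer_has_no_channels(self):
        assert d.cid_channels(d.insulin_species(1, 7)) == []

    def test_symmetric_dimer_split_indistinguishable(self):
        parent = d.insulin_species(2, 6)
        sym = [ch for ch in d.cid_channels(parent) if ch.fragments == ((1, 3), (1, 3))]
        assert len(sym) == 1
        assert sym[0].parent_indistinguishable
        asym = [ch for ch in d.cid_channels(parent) if ch.fragments != ((1, 3), (1, 3))]
        assert all(not ch.parent_indistinguishable for ch in asym)


class TestClassifyPeak:
    def test_dimer_contamination_is_aggromer_mixture(self):
        # the classic case: a nominal [M+3H]3+ peak whose isotope fine
        # structure carries a [2M+6H]6+ component
        mono = d.insulin_species(1, 3)
        v = classify_peak(
            mono,
            atd_family_count=2,
            pattern_weights={"[1M+3H]3+": 0.7, "[2M+6H]6+": 0.3},
        )
        assert v.verdict == d.Verdict.AGGROMER_MIXTURE
        assert v.early_peak_species == "[2M+6H]6+"

    def test_pure_pattern_means_conformers(self):
        mono = d.insulin_species(1, 3)
        v = classify_peak(
            mono,
            atd_family_count=2,
            pattern_weights={"[1M+3H]3+": 0.99, "[2M+6H]6+": 0.01},
            cid_fragments_observed=[],
        )
        assert v.verdict == d.Verdict.CONFORMERS

    def test_any_fragment_from_nominal_monomer_means_multimer(self):
        mono = d.insulin_species(1, 3)
        v = classify_peak(mono, cid_fragments_observed=[(1, 1)])
        assert v.verdict == d.Verdict.AGGROMER_MIXTURE

    def test_contradictory_streams_undetermined(self):
        mono = d.insulin_species(1, 3)
        v = classify_peak(
            mono,
            pattern_weights={"[1M+3H]3+": 1.0, "[2M+6H]6+": 0.0},
            cid_fragments_observed=[(1, 1)],
        )
        assert v.verdict == d.Verdict.UNDETERMINED

    def test_no_evidence_undetermined(self):
        v = classify_peak(d.insulin_species(1, 3), atd_family_count=3)
        assert v.verdict == d.Verdict.UNDETERMINED
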