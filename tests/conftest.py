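import warnings

import pytest

import driftms as d


@pytest.fixture(scope="session")
def instrument():
    return d.InstrumentConfig()


@pytest.fixture(scope="session")
def insulin_monomer_formula():
    return d.elemental_formula(d.insulin_chains(), disulfides=3, n=1)


@pytest.fixture(scope="session")
def dimer_7plus():
    return d.insulin_species(2, 7)


DIMER_CCS = (1217.0, 1324.0, 1563.0, 1701.0)
DIMER_ABUNDANCE = (0.50, 0.27, 0.15, 0.08)


@pytest.fixture(scope="session")
def dimer_truth(dimer_7plus):
    """Four-family insulin dimer ground truth: the most compact family is
    the most abundant, the most extended the least, as seen for [2M+7H]7+."""
    return d.GroundTruth(
        species=dimer_7plus,
        families=tuple(
            d.FamilyTruth(ccs, ab) for ccs, ab in zip(DIMER_CCS, DIMER_ABUNDANCE)
        ),
    )


@pytest.fixture(scope="session")
def dimer_atd(dimer_truth, instrument):
    return d.simulate_atd_set(dimer_truth, instrument)


@pytest.fixture(scope="session")
def dimer_families(dimer_atd, dimer_7plus):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return d.analyse_atd_set(dimer_atd, z=7, ion_mass=dimer_7plus.mass_avg)
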