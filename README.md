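# driftms

Drift-tube ion-mobility mass spectrometry (IM-MS) analysis of protein
oligomer conformers, with a built-in synthetic instrument for validating
the full inference chain.

## The scientific problem

Early amyloid aggregation proceeds through transient soluble oligomers.
Native electrospray IM-MS can separate these oligomers by both
mass-to-charge and shape: each `[nM + zH]^z+` ion drifts through a
buffer-gas-filled tube at a speed set by its collision cross section
(CCS), so one m/z-selected peak can reveal several coexisting conformer
families as distinct arrival-time modes. Three complications make the
analysis non-trivial:

1. **Overlapping conformers.** Arrival-time distributions (ATDs) are
   multimodal mixtures that must be deconvolved, and the components must
   be tracked consistently across drift voltages before a mobility — and
   hence a CCS — can be assigned to each family.
2. **Aggromer degeneracy.** `[2M+6H]^6+` has exactly the same average
   m/z as `[M+3H]^3+`; every nominal peak hides a ladder of coincident
   higher oligomers. Only the isotopologue stick spacing (1.00336/z) or
   collision-induced dissociation (CID) can tell them apart.
3. **Gas-phase artefacts.** Charge states above the de la Mora
   (Rayleigh) limit `z_R = 0.0778·√M` may owe their extended shapes to
   coulombic unfolding rather than solution structure and must be
   flagged before conformer populations are interpreted.

`driftms` implements this chain end to end: a synthetic drift-tube
generator with exact ground truth; Gaussian-mixture ATD deconvolution;
cross-voltage family tracking and `P/V` regression to reduced mobility;
Mason–Schamp conversion to CCS; isotope-pattern NNLS decomposition and
CID channel enumeration for species assignment; the Rayleigh charge
screen; and structure-side observables (radius of gyration,
projection-approximation CCS, Kabsch RMSD, Rg–CCS calibration) to
connect atomistic models to the measured cross sections. Bovine insulin
(chains A/B, 3 disulfides) is packaged as the reference system.

See `docs/methods.md` for the model, parameters and numerical choices.

## Worked example

Simulate a four-conformer insulin dimer experiment with counting noise
and recover the family CCS values:

```python
import driftms as d

sp = d.insulin_species(2, 7)                       # [2M+7H]7+
truth = d.GroundTruth(
    species=sp,
    families=(
        d.FamilyTruth(1217.0, 0.50),
        d.FamilyTruth(1324.0, 0.27),
        d.FamilyTruth(1563.0, 0.15),
        d.FamilyTruth(1701.0, 0.08),
    ),
    noise=d.NoiseModel(peak_counts=2000, baseline_counts=2, seed=1),
)
atd = d.simulate_atd_set(truth, d.InstrumentConfig())
for fam in d.analyse_atd_set(atd, z=sp.z, ion_mass=sp.mass_avg):
    print(f"rank {fam.rank}: CCS = {fam.ccs:7.1f} A^2  "
          f"abundance = {fam.abundance:.3f}  K0 = {fam.fit.K0:.4f} cm^2/V/s")
```

Output:

```
rank 1: CCS =  1215.0 A^2  abundance = 0.497  K0 = 3.0779 cm^2/V/s
rank 2: CCS =  1318.9 A^2  abundance = 0.273  K0 = 2.8355 cm^2/V/s
rank 3: CCS =  1565.7 A^2  abundance = 0.151  K0 = 2.3886 cm^2/V/s
rank 4: CCS =  1706.6 A^2  abundance = 0.079  K0 = 2.1913 cm^2/V/s
```

The same chain is available from the command line (`driftms run
--config run.yaml`), which writes `families.tsv`, `ccs.tsv`,
`verdicts.json`, `limits.tsv`, `composite.json` and `run.log` for a
YAML-configured multi-species run; `driftms simulate`, `deconvolve`,
`ccs`, `assign`, `limits` and `structure` expose the individual stages.

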