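# Methods

This note records the physical model behind `driftms`, the parameters it
exposes, what the synthetic-instrument generator does and does not
emulate, and the numerical choices made in the analysis chain.

## Physical model

### Drift and arrival time

An ion of charge `z` drifting through a tube of length `L` under a
uniform field `V/L` in a buffer gas at pressure `P` and temperature `T`
moves with velocity `K·V/L`, where `K` is its mobility. Mobilities are
normalised to standard conditions as the reduced mobility

    K0 = K · (P / 760 Torr) · (273.15 K / T)

The arrival time recorded by the detector is the drift time plus a
mass-dependent dead time spent in the transfer optics outside the drift
region:

    t(V) = t_dead(m/z) + L² / (K · V),      t_dead = c · sqrt(m/z)

Because `t` is linear in `P/V`, an ordinary least-squares regression of
arrival time on `P/V` across several drift voltages separates the two
terms: the intercept is the dead time and the slope gives `K0`. The
dead-time coefficient `c` is modelled as voltage-invariant, which is what
makes the intercept meaningful.

### Mason–Schamp conversion

Reduced mobility converts to a collision cross section (CCS, Ω) via the
Mason–Schamp equation in its low-field form:

    Ω = (3 z e / 16 N0) · sqrt(2π / (μ kB T)) · (1 / K0)

with `μ` the ion–buffer-gas reduced mass, `N0` the Loschmidt number
(buffer-gas number density at standard conditions), and CODATA values for
all constants. A useful compact check: Ω ≈ 1.851·10⁴ · z / (K0 · sqrt(μT))
Å² with `K0` in cm²V⁻¹s⁻¹, `μ` in u, `T` in K; for `K0 = 1`, `z = 1`,
`T = 300 K`, `μ = 4 u` this gives 534.3 Å².

### Peak shape

Each conformer family contributes a Gaussian arrival-time peak whose
width is set by the diffusion-limited resolving power

    t / Δt_FWHM = sqrt(z e V / (16 ln2 · kB T))

so `σ_t = t_drift / (2.3548 · R) · width_inflation`. The
`width_inflation` factor (default 2) represents the gate width, space
charge and field inhomogeneity that broaden real peaks beyond the
diffusion limit.

### Isotopologue fine structure

The isotopologue distribution of an `[nM + zH]^z+` ion is computed by
iterated convolution of per-element abundance vectors indexed by
added-neutron count (IUPAC 2021 abundances for H, C, N, O, S), using
binary exponentiation for the per-element powers. Sticks are placed at

    m/z(k) = (m_mono + k · 1.0033548378 u + z · m_proton) / z

i.e. equally spaced by the neutron–proton mass difference over charge.
The true spacing varies by a few 10⁻⁴ u between isotopologues of
different elements; the equal-spacing approximation is far below the
resolving powers simulated here and keeps the pattern a rigid comb,
which the mixture decomposition relies on.

Because the average m/z of `[knM + kzH]^kz+` is identical to that of
`[nM + zH]^z+` for every integer `k`, nominal assignments are degenerate
("aggromers"). Two evidence streams break the degeneracy:

* **fine structure** — stick spacing is `1.00336/z`, so the candidates'
  broadened template patterns are linearly independent and a
  non-negative least-squares (NNLS) fit of the observed profile on the
  candidate templates yields mixture weights;
* **collision-induced dissociation** — a non-covalent multimer fissions
  into sub-oligomers that partition mass and charge exactly
  (`n1+n2 = n`, `z1+z2 = z`, all ≥ 1), so an observed fragment can
  require a higher-order parent than the nominal assignment.

### Charge limit

The empirical de la Mora (Rayleigh) relation `z_R = 0.0778·sqrt(M_R)`
(`M_R` in u) bounds the charge a compact globular ion retains from a
electrospray droplet. Species observed above `z_R` are flagged: their
conformational spread may reflect coulombically driven gas-phase
unfolding rather than solution structure.

### Structure-side observables

* Radius of gyration: mass-weighted RMS distance from the centre of
  mass.
* Projection-approximation (PA) CCS: orientation-averaged projected area
  of the union of atom spheres (Bondi radius + probe radius), averaged
  over uniformly random rotations. PA systematically underestimates
  trajectory-method CCS for concave surfaces because it ignores
  multiple scattering; the offset is documented, not corrected.
* Kabsch RMSD: optimal proper-rotation superposition via SVD with the
  determinant sign correction.
* Rg–CCS calibration: OLS line with Pearson r; quartile response: sort
  by Rg, split into four near-equal bins (compact → extended), average
  the response per bin.
* Cuboid Rg `sqrt((a²+b²+c²)/12)` for slab/rod protofilament estimates.

## Parameters

| Parameter | Units | Default | Rationale |
|---|---|---|---|
| `drift_length` | cm | 5.1 | short-drift-tube geometry typical of the instruments this emulates |
| `pressure` | Torr | 3.5 | helium drift pressure in the same regime |
| `temperature` | K | 300 | ambient drift cell |
| `buffer_gas_mass` | u | 4.002602 | helium |
| `voltages` | V | 25, 32, 39, 46, 53, 60 | six points spanning >2× in `P/V` for a stable two-parameter regression |
| `dead_time_coeff` | µs per sqrt(m/z) | 2.0 | gives dead times of a few tens of µs at protein m/z, small but non-negligible against ms drift times |
| `width_inflation` | – | 2.0 | broadening beyond the diffusion limit (gate width etc.) |
| `bin_width` | µs | 5.0 | keeps ≥2 bins per σ for every simulated species/voltage; the generator refuses configurations where `bin_width > σ_min/2` |
| `peak_counts` | counts | 0 (noise-free) | Poisson scale: tallest bin expectation; 0 disables noise |
| `min_snr` | – | 3.0 | seed peaks must clear 3× the MAD noise scale |
| `k_max` | – | 4 | at most four conformer families per species |
| `aggromer_threshold` | weight | 0.05 | secondary species below 5% pattern weight is treated as absent |
| `resolving_power` | – | 5·10⁴ | FT-ICR-class resolution needed to separate sticks at z ≈ 6–7 |
| `probe_radius` | Å | 1.0 | helium probe for PA CCS |
| PA grid | Å | 0.1 | rasterisation cell for the projected disk union |

## What the generator emulates — and does not

Emulated: per-voltage arrival-time histograms with bin-integrated
Gaussian components (exact bin areas via the normal CDF), ground-truth
family CCS → centroid mapping through the full physical chain,
m/z-dependent dead time, diffusion-limited width scaling with voltage,
Poisson counting noise plus a flat Poisson baseline, isotopologue
profiles at finite resolving power, and binary CID stick spectra.

Not emulated: ion transmission/detection efficiency varying with m/z or
mobility, gate depletion and space-charge distortions (beyond a constant
width inflation), peak tailing or non-Gaussian shapes, mobility
dependence on the electric field (low-field limit assumed), chemical
noise and background ions, isotopologue-resolved ATDs, fragment-ion CCS,
and any solution-phase kinetics: the generator produces snapshots, not
aggregation time courses.

## Numerical choices

* **Bin integration.** Components are integrated over bins with the
  normal CDF (`ndtr`), not sampled at bin centres, so areas are exact
  and the fitted area parameter is in total counts.
* **Mixture fitting.** Nonlinear least squares (`scipy`, trust-region
  reflective) with an analytic Jacobian, a fitted flat-baseline
  parameter, `x_scale='jac'` and tolerances of 1e-12. Residuals are
  weighted by `1/sqrt(max(y, 1))`, the Poisson-counting (Neyman
  chi-square) approximation; for noise-free sub-unit profiles the
  weights collapse to 1.
* **Model order.** Fits with k = 1..4 components are compared by the
  Bayesian information criterion `chi² + (3k+1)·ln(n)`; the smallest k
  within one penalty unit of the minimum is kept (an unweighted
  RSS-improvement elbow overfits counting noise, where only a few dozen
  bins carry signal). Numerically exact fits short-circuit.
* **Seeding.** Initial components come from local maxima above the MAD
  threshold; each k also tries residual peeling from the best (k−1) fit.
  Traces are processed from high to low voltage, and each fit seeds the
  next trace with centroids scaled by the voltage ratio and widths by
  ratio^1.5 — overlapping low-voltage mixtures stay on the same solution
  branch.
* **Family tracking.** Components are matched across voltages by
  arrival-time rank, which is voltage-invariant because `t ∝ 1/K` at
  fixed V. Families seen at fewer than two voltages are dropped with a
  warning.
* **Composite distributions.** Families pooled per oligomer order as
  Gaussians at their CCS with width `max(stderr, 1% CCS)` and
  area-fraction weights renormalised within the order.
* **NNLS decomposition.** Candidate templates are checked for rank
  deficiency (pairwise normalised Gram entries > 1−1e-12 rejected)
  before `scipy.optimize.nnls`.
* **PA CCS.** Disk-union area by rasterisation on a 0.1 Å grid;
  orientation average over `scipy` uniform random rotations with the
  Monte-Carlo standard error reported.
* **Determinism.** One global seed fans out per species through
  `numpy.random.SeedSequence.spawn`; identical configurations produce
  byte-identical numeric artifacts.

## Limitations

* The generator and the analysis share the same peak model; recovery
  tests therefore validate the inference chain, not the model's fidelity
  to any physical instrument.
* Rank-based family tracking assumes no family appears/disappears
  between adjacent voltages out of rank order; heavily overlapped
  low-voltage traces rely on the cross-voltage seeding heuristic.
* The equal-spacing isotope comb and aggregated (unit-neutron)
  isotopologue distribution ignore isotopic fine splitting within a
  nominal mass; at resolving powers ≫ 10⁶ this would matter.
* PA CCS is a lower bound relative to trajectory-method values for
  non-convex shapes; no empirical scaling factor is applied.
* The de la Mora screen uses the average (not monoisotopic) mass and the
  single empirical coefficient 0.0778; it is a flag, not a verdict.
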