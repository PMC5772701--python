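# Methods

## Scope of the model

`smkbnct` implements the stochastic microdosimetric kinetic (SMK) survival
model for mixed BNCT fields, with the nucleus-dose stochasticity treated
exactly (compound-Poisson), a dose-protraction correction of the quadratic
term, and intra-/intercellular ¹⁰B heterogeneity.  The overkill saturation
parameter of earlier SMK variants is deliberately absent: within the dose
range the model targets, higher saturation thresholds always fit better, so
the parameter adds nothing.  Nontargeted/bystander terms and cell-cycle
resolved sensitivity are out of scope.

## Charged-particle physics

Transport is straight-line CSDA in unit-density water: no energy straggling,
no angular scattering, no nuclear interactions, no particle-by-particle
δ-ray transport.  For the ≤ 2 MeV capture fragments (ranges ≤ 10 µm) lateral
scattering displaces tracks by far less than a nucleus radius, so the
two-fragment back-to-back picture is adequate for nucleus-scale energy
deposition.  The tissue is treated as water; the reference composition
(H 11.1%, C 12.6%, N 2.1%, O 74.2% by weight) differs from water by less
than the stopping-table uncertainty itself.

Stopping tables (`src/smkbnct/data/stopping_*.tsv`, generated by
`scripts/make_stopping_tables.py`) are semi-empirical: a hand-encoded
PSTAR-like proton node curve joined to the Bethe formula (I = 75 eV) above
0.5 MeV; heavier ions by Barkas effective-charge velocity scaling plus ZBL
universal nuclear stopping.  Each species is normalized to one published
CSDA anchor — proton 24 µm at 1 MeV, ⁷Li 4.0 µm at 0.84 MeV, α 41 µm at
5.49 MeV — which reproduces the α range of ≈ 7.7 µm at 1.47 MeV and a Bragg
peak of ≈ 230 keV/µm near 0.5–0.8 MeV.  Carbon recoils carry no anchor;
their sub-micron ranges make deposits effectively local.  The electron table
is a crude collision-stopping curve for the optional photon-component path;
the intended photon route is an imported PD or electron spectrum file.
Energy–range interpolation is piecewise log-log linear with an exact
inverse, so CSDA additivity holds to round-off (property-tested at 1e-9 MeV).

## Lattice geometry and scoring

Cells are 5 µm spheres with 3 µm nuclei on an 11×11×11 cubic lattice.  The
nucleus centre sits 1.5 µm from the cell centre — the mean distance of a
nucleus placed at random in the cytoplasm — along +z for every cell by
default (a per-cell random orientation mode exists; the acceptance runs use
the default).  The lattice pitch is 10 µm, i.e. touching spheres, a choice
that fixes the intracellular volume fraction at π/6 = 0.524 and, combined
with the measured intra/extracellular concentration ratios (3.2 for BPA,
0.86 for BSH), yields the standard compartment weights N_c/N_e = 0.78/0.22
and N_s/N_e = 0.49/0.51.

Sources are confined to the central lattice cell (uniform by volume in
nucleus / cytoplasm / extracellular space, uniform by area on the cell
sphere) and all 1331 nuclei are scored; by translational symmetry this is
equivalent to scoring one nucleus with sources everywhere, and the fragment
ranges (≤ 10 µm) make edge effects negligible.  An *event* is a history
depositing nonzero energy in a given nucleus; z_n histograms use 400
log-spaced bins over 1e-4–10 Gy.  For volume-uniform sources the mean
nucleus-summed specific energy per history equals the kerma per history
(charged-particle equilibrium), verified to 2% in the suite.

## Domain PDs: the chord surrogate and its limits

Domain PDs f_d,1(z_d) are built statistically (domains are never tiled into
the geometry): nucleus track segments are sampled in proportion to length,
a µ-randomness chord ℓ ~ ℓ/(2 r_d²) on [0, 2 r_d] is drawn, and the CSDA
deposit over ℓ at the segment's midpoint energy becomes z_d.  For a
constant-LET track this reproduces z̄_dD = (3/2) L r_d / m exactly
(oracle-tested).  The surrogate ignores δ-ray escape/influx and energy-loss
straggling at the ~0.2 µm scale, which a track-structure-based
microdosimetric function would include; absolute z̄_dD (hence the β₀ z̄_dD
term) therefore differs from track-structure values, and externally computed
domain PDs can be imported through the PD file path as the authoritative
route.  Ratio-type outputs (κ_B, CBE ratios between compounds, orderings in
σ) are insensitive to this surrogate, which is why the benchmark quantities
are ratios, bounds and closed forms.  Chords are not clipped at the nucleus
boundary (r_d ≪ nucleus radius).

## Compound-Poisson convolution

f_n(z_n, z̄_n) is evaluated on a uniform grid of 2¹⁴ points (2¹²–2¹³ in the
fitting loop) spanning 1.5× the mean + 5σ and the single-event support.
Single-event masses are collected at the lattice points j·dz (the zero-event
atom sits exactly at z = 0) and the full Poisson sum is applied in one step
via characteristic-function exponentiation, exp(λ(φ−1)) — identical to the
k-sum for every λ and fast up to the λ ~ 10³–10⁴ of therapeutic doses.  The
point-lattice representation matters: collecting masses at bin midpoints
shifts a k-fold convolution by k·dz/2, a bias the KS- and λ→∞-limit oracles
catch immediately.  The first moment of the output equals κD to grid
resolution by construction (λ = κD / z̄_F,discrete).

## Heterogeneity, protraction, effectiveness

Intercellular spread multiplies the intracellular weights (N_n, N_c, N_s) by
x without renormalization, so κ_B(x) is linear in x and the extracellular
share is unaffected.  The Gaussian form is truncated at x = 0 and
renormalized (clipped mass < 5% for σ ≤ 0.6; the mean is not re-centred) and
integrated with 64-point Gauss–Legendre on [0, 1 + 6σ]; the double-peak form
averages x = 1 ± σ.  G uses the full irradiation time T = D/rate of each
condition as a single factor; intra-irradiation ¹⁰B kinetics are out of
scope.  Component-level RBE/CBE tables are computed acute (G = 1);
condition-level values use each condition's T.  The tumour/blood
concentration rescaling of CBE is a single multiplicative option left at 1.
α_γ = α₀ + β₀ z̄_dD(photon); the bundled reference value 0.0634 Gy⁻¹ is used
directly where a photon field is only a reference, because the photon
z̄_dD from the crude electron option is surrogate-dependent.

## Parameter fitting

χ² = Σ[(S_exp − S_cal)/ΔS]² with heterogeneity off, matching how the
reference parameters were determined.  For each r_d on the 0.10–0.30 µm
grid, (α₀, β₀, γ₀) are fitted by Levenberg–Marquardt in log space
(positivity); the best r_d is the grid argmin.  The compound-Poisson tables
depend only on (condition, dose) and are precomputed, so an LM iteration is
a weighted exponential sum.  Starts: a deterministic γ₀ ladder
(0.2, 1, 5, 25 h⁻¹) at canonical LQ magnitudes (α 0.05, β 0.01), plus a
data-driven start from a quadratic fit to −ln SF and seeded multiplicative
jitters — γ₀ is the least-identified parameter and the ladder prevents the
G→0 local minimum.  Uncertainties come from the LM Jacobian (log-space
covariance scaled by χ²/dof); R̄² is computed on SF, the χ² weighting space.

## Synthetic data

The clonogenic measurements behind the reference parameters are not
deposited, so validation uses synthetic records: SF computed through the
full forward model, perturbed by multiplicative lognormal noise with
ΔS = sd·SF.  The default design mirrors the reference experiments — a
⁶⁰Co-like photon reference at 2 Gy/min (doses 1–16 Gy, sampled twice as
densely because it is the lever for α₀ and β₀), the bare neutron beam at
1.56 Gy/h total (0.90 neutron + 0.66 photon; hours-long exposures pin γ₀),
and a BSH-like condition (κ = 0.51, boron-dominated domain spectrum) — with
toy PDs whose z̄_dD magnitudes (photon 2.6 Gy, beam 45 Gy, boron ~190 Gy at
r_d = 0.24 µm) follow the lattice simulation, scaling as (0.24/r_d)² for
ion-dominated fields and ∝ 1/r_d for photons (δ-ray spreading weakens the
geometric scaling).  What passing recovery tests show is that the estimator
is unbiased and precise *under this design*: 20 records at 10% noise give
median errors ≈ 12% (α₀) and ≈ 3% (β₀), while γ₀ remains poorly determined
(median ~90%) — consistent with the large γ₀ uncertainty of the real
experiment.  They do not show that real in-vivo data of similar size would
pin the parameters equally well; real designs have fewer low-dose photon
points and correlated dosimetry errors the noise model omits.

The bundled hydrogen/photon source spectra
(`spectrum_*_synthetic.tsv`) are simplified synthetic stand-ins (softened
recoil-proton and Compton-like electron continua) that keep those pathways
exercisable end-to-end; quantitative work on real beams should import
measured or externally simulated spectra or PDs.

## Problem sizes and numerical choices

Acceptance runs use 2×10⁵ histories per source localization (1.5×10⁵ for
the concentric variant), 10⁶ histories for the maximum-z_n scan and 2×10⁵
domain-chord samples per compartment; κ_B is then stable to ±0.005 across
seeds.  The test suite uses 10⁵-history fixtures shared across tests.
Monte Carlo throughput is ~5×10⁵ histories/s on one core (vectorized
chord intersection against the 27 reachable nuclei).  Root finding for
fixed-SF doses uses bisection/Brent to 1e-4 Gy.  Degenerate inputs are
explicit errors: empty PDs, sources that cannot reach a nucleus, zero
uncertainties, unbracketed survival levels.

## Known limitations

- Absolute domain dose-means (and thus absolute β₀-term magnitudes and
  survival levels) inherit the chord-surrogate bias; import PHITS-style
  domain PDs for absolute work.
- The hydrogen/photon component defaults are synthetic spectra, not a
  beam model; nitrogen/boron components are first-principles.
- Single tissue composition (water-equivalent), no tumour-scale dose
  gradients, no normal-tissue complication modelling.
- The fitted-parameter values shipped as defaults are the published
  reference set; they are not refit here because the underlying survival
  measurements exist only as figures.
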