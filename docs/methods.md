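# Methods

`slabrefl` models specular neutron reflectometry of layered solid–liquid
interfaces — the measurement used to resolve how antibodies (IgG4) and
surface-immobilised protein A arrange themselves on silica — and the
interpretation arithmetic that turns fitted layer models into interfacial
quantities.  This note records the model, its conventions and assumptions,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate.

## Forward model

The interface is a one-dimensional stack: a semi-infinite fronting medium
(the silicon wafer the beam enters through), N uniform slabs, and a
semi-infinite backing medium (the aqueous solvent).  Each slab has a
thickness τ (Å), a scattering length density ρ (Å⁻²), and a roughness σ (Å)
describing the Gaussian width of the interface to the preceding medium.

Reflectivity is computed with the Abeles characteristic-matrix method.  For
momentum transfer Q, medium *i* has perpendicular wavevector

    k_i = sqrt(Q²/4 − 4π(ρ_i − ρ_fronting)),

taken on the complex branch with non-negative imaginary part so evanescent
regions below the critical edge need no special casing.  Interfaces carry
Fresnel coefficients damped by Névot–Croce factors exp(−2 k_i k_{i+1} σ²);
the 2×2 matrices are multiplied from the fronting side and R = |m₁₀/m₀₀|²,
clipped to [0, 1] so the total-reflection plateau is exactly 1 (matching
data normalised to unit intensity at total reflection).  A common phase
factor of each characteristic matrix cancels in that ratio, so the matrices
are applied in a factored form that halves the complex exponentials; the
result is algebraically identical.  The test suite checks the implementation
against an independently written Parratt recursion on 1000 random stacks at
1e-10 relative tolerance, and against a micro-sliced erf profile for rough
interfaces.

Conventions worth stating because the field varies on them:

- slabs are ordered from silicon toward solvent; a slab's roughness belongs
  to its fronting-side interface; `backing_roughness` is the final
  slab/solvent interface;
- roughness is a Gaussian σ, not a FWHM;
- Q is the independent variable everywhere; instrument geometry enters only
  through `q_from_angle` (Q = 4π sinθ/λ);
- SLDs are real (the materials here absorb weakly).

Névot–Croce damping rather than micro-slicing was chosen because it is the
standard slab-model treatment and accurate while σ is small compared with
the adjacent layers; `Stack` warns when a roughness exceeds a neighbouring
thickness.  SLD-depth profiles blend slab values with error functions of the
same σ, with z = 0 at the fronting/first-slab boundary.

## Resolution smearing

Instrumental resolution is a Gaussian in Q of constant relative width; the
default dQ/Q = 0.03 (σ/Q) is typical of the time-of-flight and monochromatic
reflectometers this kind of data comes from, which do not usually publish a
single number.  Because σ_Q ∝ Q, the kernel has constant width in ln Q, so
the model is evaluated exactly on a logarithmic grid oversampled at σ/6,
convolved there with the kernel truncated at ±3.5σ, and interpolated back to
the data grid.  Data files carrying a dQ column (FWHM) override the global
default with the column's median dQ/Q.

## Scattering-length-density bookkeeping

Water mixtures mix linearly in D2O volume fraction between the pure-water
endpoints (defaults 6.36×10⁻⁶ and −0.56×10⁻⁶ Å⁻²); `match_point` inverts
the rule exactly, reproducing silicon-matched water at 38 % D2O.  A
material's SLD is (b_total + n_labile·f·x·(b_D − b_H))/V with b_H = −3.739 fm
and b_D = 6.671 fm; the fraction of labile hydrogens appearing as deuterium
is the exchange fraction f (default 0.9, the usual assumption for folded
protein) times the solvent's D2O fraction x, a proportional-mixing model
that reduces to "90 % exchanged" in pure D2O and behaves sensibly in
intermediate contrasts.  All of these constants are configuration defaults
in `constants.py`, not hard-coded values.

The protein compositions shipped as presets (IgG4, rSPA) are stand-ins: the
original study computed them with an external biomolecular SLD calculator
and did not tabulate them.  The presets use standard protein bookkeeping —
volume from MW/(ρ'N_A) at ρ' = 1.42 g cm⁻³, a fully protonated SLD near
1.8×10⁻⁶ Å⁻², roughly 1.85 labile hydrogens per residue — and are free
inputs a user should replace with calculator output for quantitative work
on other proteins.

## Multi-contrast co-refinement

One structural profile is shared across curves measured in different
solvents.  Layers are parameterised by (material, φ, τ, σ) so each
contrast's layer SLD, φ·ρ_a(solvent) + (1−φ)·ρ_s(solvent), is recomputed
automatically — this coupling is what the simultaneous fit exploits, and it
makes the fitted φ exactly consistent with the volume-fraction inversion in
`metrics`.  Raw-SLD layers remain available for non-protein layers (SiO2);
the SiO2 layer is conventionally box-constrained near 3.43×10⁻⁶ Å⁻² with
thickness in [5, 20] Å, the native-oxide window.

The fit statistic is χ² = (1/N)Σ((s·R_model + b − R_obs)/dR)² per contrast,
averaged over contrasts so curves with different point counts weigh equally;
the source software's exact statistic is undocumented, so this is a package
convention, not a reproduction.  Scale s and additive background b are
per-contrast parameters; background is fitted for data reduced without
background subtraction and fixed at 0 (or the known level) otherwise.

Optimisation is a seeded differential-evolution global search (population
15 per free parameter by default; the population is evaluated through a
vectorised batch of the optical matrices) followed by a Nelder–Mead polish.
Fringe-fitting landscapes are multimodal; when the polished reduced χ²
stays above a threshold (default 1.5, far outside the ~1 ± 0.1 expected for
a correct model at these point counts) the search can be restarted from
derived seeds, keeping the best result.  Everything is deterministic given
the seed.

Uncertainties come from a residual-resampling bootstrap: standardised
residuals are resampled with replacement within each contrast (the Q grid is
a fixed design, so cases are not resampled), pseudo-data are rebuilt around
the best-fit model, and each replicate is re-polished from the best
parameters; 2.5/97.5 percentiles give the reported intervals.  Model
variants are ranked by total χ² with ties (Δχ² below 0.05 by default) broken
toward fewer layers, and bootstrap relative interval widths reported as the
robustness diagnostic.

## Interface metrics

From a fitted layer: φ = (ρ_s − ρ_l)/(ρ_s − ρ_a) (values outside [0, 1] are
flagged, not raised — fitted SLDs can overshoot); Γ = φ·τ·ρ'_p converted to
mg m⁻² (ρ'_p default 1.42 g cm⁻³ for protein); area per molecule from Γ and
the molecular weight; packing ratios against a footprint (defaults: 13,600 Å²
flat-on IgG4, 26×26 Å upright protein A cross-section).  The porous-resin
comparison treats beads as monodisperse spheres at a packing efficiency,
brackets the pore area with outer:inner area ratio bounds, and spreads the
ligand mass over it; the ligand concentration can be given directly or
derived from the dynamic binding capacity with explicit molecular weights.
Outputs are full precision with an `as_printed` 2-significant-figure helper,
because published worked examples round intermediates.

## Synthetic data

The scenario registry encodes the study's fitted structures (silica-adsorbed
antibody at two pHs, cross-linked protein A with BSA or PEG blocking, and
the antibody-loaded versions) as generating models.  Thicknesses follow the
published narrative; volume fractions and roughnesses that only appear in
unavailable table cells are best-effort assumptions recorded per scenario in
its `assumptions` field — they define reproducible test conditions, not the
original fitted truth.  Simulation adds, per contrast: dQ/Q = 0.03 Gaussian
smearing, a constant background (default 1×10⁻⁶), and Gaussian noise with
σ = max(0.02·R, background/3).  Gaussian rather than Poisson noise because
reduced reflectivity is normalised counts, where sqrt-count errors become
relative Gaussian errors; the 2 % floor stands in for the counting
statistics of a several-hour measurement.  Default Q grids are log-spaced
120 points over 0.01–0.20 Å⁻¹ (time-of-flight style) or 0.008–0.250 Å⁻¹
(monochromatic style).

What the recovery tests show — and don't.  Each scenario simulated at three
contrasts and refit from generic bounds recovers layer thicknesses within
5 % and φ within 0.03 for ≥90 % of seeds in most scenarios.  Two structural
situations sit below the information content of such data and fail that
band honestly:

- a thin dilute layer (~8 Å at φ ≈ 0.05, the hydration layer against the
  wafer): its maximum-likelihood thickness scatters by ~±0.6 Å (1σ) even
  when the optimiser is started at the truth, wider than the 5 % (±0.4 Å)
  band;
- a three-way split of a 70 Å film whose roughness (8 Å) is comparable to
  the sub-layers: the individual boundaries trade off against each other
  and only the total thickness is well determined — consistent with the
  original study quoting only the 70 Å total for that condition.

These are measurement-resolution limits, not optimiser failures (restarting
or polishing from the truth does not fix them), and real instrument data
shares them.  Synthetic data also idealise in ways real data do not: perfect
background constancy, exactly known resolution, no Q-offset or misalignment
errors, and identical structures across contrasts by construction.

## Numerical choices and degenerate inputs

- Complex square roots take the Im ≥ 0 branch; no special-casing at Q_c.
- R is clipped to [0, 1]; Névot–Croce factors can push |r| marginally above
  1 below the critical edge.
- Zero-thickness slabs and slabs matching both neighbours are exact no-ops.
- χ² requires dR > 0; files without a dR column get a 2 % relative floor
  with a warning.
- Bootstrap pseudo-data are clipped at R ≥ 0 (relevant only where the model
  is within noise of zero).
- Tie-breaks in model comparison go to fewer layers; identical variants get
  identical χ² (seeded determinism).

## Problem sizes used in the test suite

Simulated fits use 120-point curves at three contrasts; recovery experiments
run 20 seeds per scenario with a differential-evolution budget of population
8 per parameter and 45 generations plus up to three seeded restarts, and
bootstrap checks use 60–80 resamples — sizes chosen so the whole suite runs
on a laptop-class single core while leaving the statistical criteria
(coverage, recovery rates) meaningful.
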