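"""Physical constants and versioned configuration defaults.

Every number used by the package that is not a fitted quantity lives here so
it can be audited and overridden in one place.  Scattering lengths are bound
coherent values in fm; SLDs are in Å⁻² throughout the package.
"""

# Bound coherent scattering lengths, fm (1 fm = 1e-5 Å)
B_H = -3.739  # protium
B_D = 6.671   # deuterium

FM_TO_ANGSTROM = 1e-5

# Scattering length densities of the pure solvents, Å⁻²
SLD_D2O = 6.36e-6
SLD_H2O = -0.56e-6

# Substrate materials, Å⁻²
SLD_SILICON = 2.07e-6
SLD_SILICA = 3.43e-6  # amorphous native oxide on a polished Si wafer

# Default fraction of labile (exchangeable) hydrogens that trade with the
# solvent; proteins in D2O-based buffer exchange about 90 % of labile sites.
DEFAULT_EXCHANGE_FRACTION = 0.90

# Mass density assumed for globular protein, g cm^-3
PROTEIN_MASS_DENSITY = 1.42

# Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23

# Instrument-style defaults
DEFAULT_DQ_OVER_Q = 0.03          # Gaussian dQ/Q resolution width (sigma)
SMEAR_TRUNCATION_SIGMA = 3.5      # kernel truncation for resolution smearing

# Reference molecular constants used by the interface metrics
IGG4_MW_DA = 165_000.0            # IgG4 kappa molecular weight
IGG_FLAT_ON_FOOTPRINT_A2 = 13_600.0   # minimum flat-on IgG4 footprint, Å²
RSPA_CROSS_SECTION_A = 26.0       # upright protein A cross-section edge, Å
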