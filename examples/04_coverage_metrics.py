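"""From fitted layer parameters to surface coverage and molecular packing.

Walks the interpretation chain for an adsorbed antibody layer: volume
fraction 0.40 over 31 A gives the adsorbed mass per area (Gamma = phi tau
rho'), which for a 165 kDa IgG4 converts to an area per molecule and a
packing ratio against the minimum flat-on footprint.  The same arithmetic
gives the sparser immobilised protein A layer and the porous-resin
comparison.
"""

from slabrefl import (
    CoverageInputs,
    ResinSpec,
    area_per_molecule,
    packing_ratio,
    resin_comparison,
    surface_coverage,
)

# dense inner IgG layer (flat-on monolayer)
gamma = surface_coverage(CoverageInputs(phi=0.40, tau=31.0, rho_p=1.42))
area = area_per_molecule(gamma, 165_000.0)
print(f"IgG inner layer:  Gamma = {gamma:.2f} mg/m^2")
print(f"  area per molecule = {area:,.0f} A^2; "
      f"packing ratio vs 13,600 A^2 flat-on footprint = {packing_ratio(area, 13_600.0):.2f}")

# sparse immobilised protein A layer
gamma_pa = surface_coverage(CoverageInputs(phi=0.05, tau=69.0, rho_p=1.42))
area_pa = area_per_molecule(gamma_pa, 48_400.0)
print(f"\nprotein A layer:  Gamma = {gamma_pa:.2f} mg/m^2")
print(f"  area per molecule = {area_pa:,.0f} A^2; "
      f"fits ~{packing_ratio(area_pa, 26.0 * 26.0):.0f} upright 26x26 A molecules; "
      f"characteristic spacing {area_pa ** 0.5:.0f} A")

# porous affinity-resin comparison (48 mg/mL DBC, 60 um beads)
report = resin_comparison(ResinSpec(), area_per_ligand=area_pa)
lo, hi = report["coverage_bounds_mg_m2"]
print(f"\nporous resin:     {report['beads_per_mL']:.2g} beads/mL, "
      f"outer area {report['outer_area_m2']:.3f} m^2/mL")
print(f"  ligand coverage bounds {lo:.1f}-{hi:.1f} mg/m^2 "
      "(flat-surface estimate sits inside, toward the low end)")
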