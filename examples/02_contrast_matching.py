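"""Solvent contrast design: silicon-matched water and protein SLDs.

Shows the D2O/H2O mixing arithmetic: the match point that renders the
silicon substrate invisible, and how a protein's SLD moves between contrasts
as its labile hydrogens exchange with solvent deuterium (90 % exchange
assumed, scaled by the solvent's D2O fraction).
"""

from slabrefl import match_point, material_preset, material_sld, solvent_preset, water_sld
from slabrefl import constants as c

x = match_point(c.SLD_SILICON)
print(f"silicon SLD {c.SLD_SILICON * 1e6:.2f}e-6 -> match point {x * 100:.0f}% D2O "
      "(silicon-matched water)")

print("\nSLD (1e-6 / A^2) by solvent, 90% labile-H exchange:")
print(f"{'':10s} {'D2O':>7s} {'SMW':>7s} {'H2O':>7s}")
for name in ("IgG4", "rSPA"):
    mat = material_preset(name)
    row = [material_sld(mat, solvent_preset(s)) * 1e6 for s in ("D2O", "SMW", "H2O")]
    print(f"{name:10s} {row[0]:7.2f} {row[1]:7.2f} {row[2]:7.2f}")
row = [water_sld(solvent_preset(s)) * 1e6 for s in ("D2O", "SMW", "H2O")]
print(f"{'water':10s} {row[0]:7.2f} {row[1]:7.2f} {row[2]:7.2f}")
print("\nthe protein/solvent contrast is largest in D2O; SMW hides the substrate")
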