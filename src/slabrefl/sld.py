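"""Scattering-length-density bookkeeping for materials and water mixtures.

Neutron contrast variation hinges on two pieces of arithmetic: the SLD of a
D2O/H2O mixture (linear in the D2O volume fraction) and the SLD of a material
whose labile hydrogens partially exchange with solvent deuterium.  Both are
implemented here together with the inversion used to design a contrast-matched
solvent (e.g. silicon-matched water, SMW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import constants as c

__all__ = [
    "MaterialComposition",
    "SolventSpec",
    "water_sld",
    "match_point",
    "material_sld",
    "solvent_preset",
    "material_preset",
    "SOLVENT_PRESETS",
    "MATERIAL_PRESETS",
]


@dataclass(frozen=True)
class MaterialComposition:
    """Scattering bookkeeping for one molecular species.

    Parameters
    ----------
    name : str
        Label used in configs and reports.
    b_total : float
        Summed bound coherent scattering length of all atoms, in fm, with
        every labile position counted as protium.
    molecular_volume : float
        Molecular volume in Å³.
    n_labile_h : int
        Number of exchangeable (labile) hydrogens.
    mass_density : float or None
        Mass density in g cm⁻³; only needed by coverage metrics.
    """

    name: str
    b_total: float
    molecular_volume: float
    n_labile_h: int = 0
    mass_density: float | None = None

    def __post_init__(self) -> None:
        if self.molecular_volume <= 0:
            raise ValueError(f"molecular_volume must be > 0, got {self.molecular_volume}")
        if self.n_labile_h < 0:
            raise ValueError(f"n_labile_h must be >= 0, got {self.n_labile_h}")
        if self.mass_density is not None and self.mass_density <= 0:
            raise ValueError(f"mass_density must be > 0, got {self.mass_density}")


@dataclass(frozen=True)
class SolventSpec:
    """A D2O/H2O mixture described by its D2O volume fraction."""

    d2o_volume_fraction: float
    sld_pure_d2o: float = c.SLD_D2O
    sld_pure_h2o: float = c.SLD_H2O
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_volume_fraction <= 1.0:
            raise ValueError(
                f"d2o_volume_fraction must lie in [0, 1], got {self.d2o_volume_fraction}"
            )
        if not self.sld_pure_d2o > self.sld_pure_h2o:
            raise ValueError("sld_pure_d2o must exceed sld_pure_h2o")

    @property
    def sld(self) -> float:
        return water_sld(self)


def water_sld(solvent: SolventSpec) -> float:
    """SLD of a D2O/H2O mixture by linear volume mixing, Å⁻²."""
    x = solvent.d2o_volume_fraction
    return x * solvent.sld_pure_d2o + (1.0 - x) * solvent.sld_pure_h2o


def match_point(
    target_sld: float,
    sld_pure_d2o: float = c.SLD_D2O,
    sld_pure_h2o: float = c.SLD_H2O,
) -> float:
    """D2O volume fraction whose mixture SLD equals ``target_sld``.

    Exact inversion of the linear mixing rule; raises if the target lies
    outside the reachable [H2O, D2O] SLD range.
    """
    if not sld_pure_h2o <= target_sld <= sld_pure_d2o:
        raise ValueError(
            f"target SLD {target_sld:g} outside reachable range "
            f"[{sld_pure_h2o:g}, {sld_pure_d2o:g}]"
        )
    return (target_sld - sld_pure_h2o) / (sld_pure_d2o - sld_pure_h2o)


def material_sld(
    material: MaterialComposition,
    solvent: SolventSpec,
    exchange_fraction: float = c.DEFAULT_EXCHANGE_FRACTION,
) -> float:
    """SLD of the pure (unsolvated) material in the given solvent, Å⁻².

    The fraction of labile hydrogens appearing as deuterium is modelled as
    ``exchange_fraction × d2o_volume_fraction`` (proportional mixing), so a
    protein that is "90 % exchanged" in pure D2O is 90 % × 0.38 exchanged in
    silicon-matched water.  Affine in the solvent's D2O fraction.
    """
    if not 0.0 <= exchange_fraction <= 1.0:
        raise ValueError(f"exchange_fraction must lie in [0, 1], got {exchange_fraction}")
    d_fraction = exchange_fraction * solvent.d2o_volume_fraction
    b_eff_fm = material.b_total + material.n_labile_h * d_fraction * (c.B_D - c.B_H)
    return b_eff_fm * c.FM_TO_ANGSTROM / material.molecular_volume


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

SOLVENT_PRESETS: dict[str, SolventSpec] = {
    "D2O": SolventSpec(1.0, name="D2O"),
    "H2O": SolventSpec(0.0, name="H2O"),
    # silicon-matched water: 38 % D2O / 62 % H2O
    "SMW": SolventSpec(round(match_point(c.SLD_SILICON), 2), name="SMW"),
}

# Protein compositions are free inputs: replace them with biomolecular SLD
# calculator output for quantitative work.  These defaults follow standard
# protein bookkeeping:
# b_total set so the fully protonated SLD is ~1.8e-6 Å⁻², volume from
# MW/(rho' N_A) with rho' = 1.42 g cm⁻³, ~1.85 labile H per residue.
MATERIAL_PRESETS: dict[str, MaterialComposition] = {
    "IgG4": MaterialComposition(
        "IgG4", b_total=34_740.0, molecular_volume=193_000.0,
        n_labile_h=2700, mass_density=c.PROTEIN_MASS_DENSITY,
    ),
    "rSPA": MaterialComposition(
        "rSPA", b_total=9_600.0, molecular_volume=54_600.0,
        n_labile_h=765, mass_density=c.PROTEIN_MASS_DENSITY,
    ),
    # LC-SPDP heterobifunctional cross-linker (small organic, one amide NH)
    "SPDP": MaterialComposition(
        "SPDP", b_total=55.0, molecular_volume=550.0, n_labile_h=1,
    ),
}


def solvent_preset(name: str) -> SolventSpec:
    try:
        return SOLVENT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown solvent preset {name!r}; available: {sorted(SOLVENT_PRESETS)}"
        ) from None


def material_preset(name: str) -> MaterialComposition:
    try:
        return MATERIAL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown material preset {name!r}; available: {sorted(MATERIAL_PRESETS)}"
        ) from None
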