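"""Interpretation arithmetic for adsorbed-protein layer models.

From a fitted slab model these routines recover: the adsorbate volume
fraction of a layer from its SLD, φ = (ρ_s − ρ_l)/(ρ_s − ρ_a); the surface
coverage Γ = φ·τ·ρ'_p in mg m⁻²; the mean area available per adsorbed
molecule; packing ratios against a molecular footprint; and a back-of-envelope
comparison with the ligand coverage of a porous chromatography resin.

All outputs are full precision; :func:`as_printed` provides the 2-significant-
figure rounding convention used when quoting values in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants as c

__all__ = [
    "VolumeFractionInputs",
    "CoverageInputs",
    "ResinSpec",
    "VolumeFractionResult",
    "volume_fraction",
    "surface_coverage",
    "area_per_molecule",
    "packing_ratio",
    "resin_comparison",
    "as_printed",
]

# unit bridge for Γ = φ · τ[Å] · ρ'[g cm⁻³]:
#   τ: 1 Å = 1e-8 cm  →  Γ in g cm⁻²;  1 g cm⁻² = 1e7 mg m⁻²
_GAMMA_SCALE = 1e-8 * 1e7  # Å·(g cm⁻³) → mg m⁻²


def as_printed(value: float, sig_figs: int = 2) -> float:
    """Round to ``sig_figs`` significant figures (reporting convention)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, sig_figs - 1 - exponent)


@dataclass(frozen=True)
class VolumeFractionInputs:
    """SLDs entering the volume-fraction inversion, all in Å⁻²:
    solvent ρ_s, fitted layer ρ_l, pure adsorbate ρ_a."""

    rho_s: float
    rho_l: float
    rho_a: float

    def __post_init__(self) -> None:
        if self.rho_s == self.rho_a:
            raise ValueError(
                "rho_s equals rho_a: contrast-degenerate, volume fraction undefined"
            )


@dataclass(frozen=True)
class VolumeFractionResult:
    phi: float
    physical: bool  # False flags φ outside [0, 1] (suspect but not fatal)

    def __float__(self) -> float:
        return self.phi


@dataclass(frozen=True)
class CoverageInputs:
    """Volume fraction φ, layer thickness τ [Å] and protein mass density
    ρ'_p [g cm⁻³]."""

    phi: float
    tau: float
    rho_p: float = c.PROTEIN_MASS_DENSITY

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.rho_p <= 0:
            raise ValueError(f"rho_p must be > 0, got {self.rho_p}")


@dataclass(frozen=True)
class ResinSpec:
    """Porous affinity-resin description for the coverage comparison.

    ligand_conc may be given directly (mg mL⁻¹) or derived from the dynamic
    binding capacity as DBC × ligand_mw / igg_mw (a 1:1 binding assumption).
    area_ratio_bounds are the (low, high) outer-surface : inner-pore area
    ratios of the beads.
    """

    dbc: float = 48.0
    bead_diameter_um: float = 60.0
    packing_efficiency: float = 0.75
    area_ratio_bounds: tuple[float, float] = (60.0, 800.0)
    ligand_conc: float | None = 13.0
    ligand_mw: float | None = None
    igg_mw: float = c.IGG4_MW_DA

    def __post_init__(self) -> None:
        for name in ("dbc", "bead_diameter_um", "packing_efficiency", "igg_mw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.area_ratio_bounds
        if not 0 < lo <= hi:
            raise ValueError("area_ratio_bounds must satisfy 0 < low <= high")
        if self.ligand_conc is None and self.ligand_mw is None:
            raise ValueError("give ligand_conc directly or ligand_mw to derive it")

    @property
    def effective_ligand_conc(self) -> float:
        if self.ligand_conc is not None:
            return self.ligand_conc
        return self.dbc * self.ligand_mw / self.igg_mw


def volume_fraction(inputs: VolumeFractionInputs) -> VolumeFractionResult:
    """Adsorbate volume fraction φ = (ρ_s − ρ_l)/(ρ_s − ρ_a).

    Exactly inverts the mixing construction ρ_l = φ·ρ_a + (1−φ)·ρ_s.  Values
    outside [0, 1] are returned with ``physical=False`` rather than raised:
    fitted SLDs can slightly overshoot the pure-component endpoints.
    """
    phi = (inputs.rho_s - inputs.rho_l) / (inputs.rho_s - inputs.rho_a)
    return VolumeFractionResult(phi=phi, physical=0.0 <= phi <= 1.0)


def surface_coverage(inputs: CoverageInputs) -> float:
    """Surface coverage Γ = φ·τ·ρ'_p in mg m⁻²."""
    return inputs.phi * inputs.tau * inputs.rho_p * _GAMMA_SCALE


def area_per_molecule(gamma: float, molecular_weight: float) -> float:
    """Mean interfacial area per adsorbed molecule, Å².

    Γ [mg m⁻²] → molecules m⁻² via N_A/MW; inverted and converted with
    1 m² = 1e20 Å².
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if molecular_weight <= 0:
        raise ValueError(f"molecular_weight must be > 0, got {molecular_weight}")
    molecules_per_m2 = gamma * 1e-3 * c.N_AVOGADRO / molecular_weight
    return 1e20 / molecules_per_m2


def packing_ratio(available_area: float, footprint: float) -> float:
    """How many molecular footprints fit in the available area per molecule."""
    if footprint <= 0:
        raise ValueError(f"footprint must be > 0, got {footprint}")
    return available_area / footprint


def resin_comparison(spec: ResinSpec, area_per_ligand: float | None = None) -> dict:
    """Ligand surface coverage implied by a porous resin's binding capacity.

    Beads are treated as monodisperse spheres at the given packing
    efficiency; the inner pore area is bracketed by the outer-area ratio
    bounds, and the ligand mass per mL is spread over that area.  The upper
    area bound gives the lower coverage bound and vice versa.  If
    ``area_per_ligand`` (Å²) is given, its square root is reported as a
    characteristic spacing length.
    """
    radius_cm = spec.bead_diameter_um * 1e-4 / 2.0
    bead_volume = 4.0 / 3.0 * math.pi * radius_cm**3        # cm³
    beads_per_ml = spec.packing_efficiency / bead_volume
    outer_area_m2 = beads_per_ml * 4.0 * math.pi * radius_cm**2 * 1e-4  # cm²→m²
    lo_ratio, hi_ratio = spec.area_ratio_bounds
    inner_area_bounds = (outer_area_m2 * lo_ratio, outer_area_m2 * hi_ratio)
    ligand = spec.effective_ligand_conc                      # mg per mL resin
    coverage_bounds = (ligand / inner_area_bounds[1], ligand / inner_area_bounds[0])
    report = {
        "beads_per_mL": beads_per_ml,
        "outer_area_m2": outer_area_m2,
        "inner_area_bounds_m2": inner_area_bounds,
        "coverage_bounds_mg_m2": coverage_bounds,
        "ligand_conc_mg_per_mL": ligand,
    }
    if area_per_ligand is not None:
        report["characteristic_length_A"] = math.sqrt(area_per_ligand)
    return report
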