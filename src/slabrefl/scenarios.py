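"""Synthetic multi-contrast reflectivity experiments from named scenarios.

Each scenario encodes a fitted interfacial structure from the IgG4 / silica /
immobilised-protein-A adsorption study this package models: a SiO2-coated
silicon wafer carrying protein layers of stated thickness and volume
fraction, measured in up to three water contrasts (D2O, H2O and
silicon-matched water).  Layer thicknesses follow the published narrative;
volume fractions and roughnesses that are only tabulated in figure tables not
available here are best-effort assumptions and are flagged per scenario —
they define reproducible test conditions, not the original fitted truth.

Simulated curves carry counting-statistics-style Gaussian noise with a
relative error floor, a constant instrumental background, and Gaussian
dQ/Q resolution smearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as c
from .sld import SolventSpec, material_preset, solvent_preset, water_sld
from .slab import ReflectivityCurve, Slab, Stack, fwhm_dq, smeared_reflectivity
from .cofit import ContrastExperiment, FitParameter, FitProblem, LayerModel

__all__ = [
    "LayerSpec",
    "ScenarioSpec",
    "NoiseModel",
    "SCENARIOS",
    "scenario_names",
    "get_scenario",
    "build_scenario",
    "simulate_experiment",
    "simulate_scenario",
    "default_q_grid",
    "recovery_problem",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a scenario: either a solvated material at volume fraction
    phi, or a raw SLD (SiO2)."""

    name: str
    thickness: float
    roughness: float = 3.0
    material: str | None = None
    phi: float | None = None
    sld: float | None = None

    def __post_init__(self) -> None:
        if (self.material is None) == (self.sld is None):
            raise ValueError(f"layer {self.name}: give exactly one of material/sld")
        if self.material is not None and self.phi is None:
            raise ValueError(f"layer {self.name}: material layers need phi")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    description: str
    layers: tuple[LayerSpec, ...]
    contrasts: tuple[str, ...] = ("D2O", "H2O", "SMW")
    fronting_sld: float = c.SLD_SILICON
    backing_roughness: float = 5.0
    exchange_fraction: float = c.DEFAULT_EXCHANGE_FRACTION
    # which layer values are package assumptions rather than published numbers
    assumptions: tuple[str, ...] = ()


@dataclass(frozen=True)
class NoiseModel:
    """Measurement emulation: σ = max(relative_error_floor·R, background/3),
    a constant additive background, and Gaussian dQ/Q smearing."""

    relative_error_floor: float = 0.02
    background_level: float = 1e-6
    dq_over_q: float = c.DEFAULT_DQ_OVER_Q
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("relative_error_floor", "background_level", "dq_over_q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_SIO2 = LayerSpec("sio2", thickness=10.0, roughness=3.0, sld=c.SLD_SILICA)


def _protein(name, thickness, phi, material="IgG4", roughness=5.0) -> LayerSpec:
    return LayerSpec(name, thickness, roughness, material=material, phi=phi)


SCENARIOS: dict[str, ScenarioSpec] = {
    "bare_wafer": ScenarioSpec(
        "bare_wafer",
        "SiO2-coated silicon wafer in buffer, no adsorbate",
        layers=(_SIO2,),
        contrasts=("D2O", "H2O"),
        backing_roughness=3.0,
        assumptions=("sio2 thickness 10 Å is the 'typically close to 10 Å' value",),
    ),
    "igg_silica_ph4_adsorbed": ScenarioSpec(
        "igg_silica_ph4_adsorbed",
        "IgG4 adsorbed to silica at pH 4.1, protein solution present",
        layers=(
            _SIO2,
            _protein("wafer_proximal", 8.0, 0.05),
            _protein("inner_protein", 31.0, 0.40),
            _protein("outer_protein", 53.0, 0.05),
        ),
        contrasts=("D2O", "H2O"),
        assumptions=("roughness values",),
    ),
    "igg_silica_ph4_rinsed": ScenarioSpec(
        "igg_silica_ph4_rinsed",
        "IgG4 on silica at pH 4.1 after buffer rinse (outer layer 53→31 Å)",
        layers=(
            _SIO2,
            _protein("wafer_proximal", 8.0, 0.05),
            _protein("inner_protein", 31.0, 0.40),
            _protein("outer_protein", 31.0, 0.05),
        ),
        contrasts=("D2O", "H2O"),
        assumptions=("roughness values",),
    ),
    "igg_silica_ph62": ScenarioSpec(
        "igg_silica_ph62",
        "IgG4 adsorbed to silica at pH 6.2 (70 Å total, denser, rougher)",
        layers=(
            _SIO2,
            _protein("wafer_proximal", 15.0, 0.16, roughness=8.0),
            _protein("inner_protein", 30.0, 0.45, roughness=8.0),
            _protein("outer_protein", 25.0, 0.16, roughness=8.0),
        ),
        contrasts=("D2O", "H2O"),
        backing_roughness=8.0,
        assumptions=("layer split 15/30/25 Å of the 70 Å total", "roughness values"),
    ),
    "rspa_crosslinked": ScenarioSpec(
        "rspa_crosslinked",
        "rSPA cross-linked to amino-silylated silica via SPDP",
        layers=(
            _SIO2,
            _protein("spdp", 20.0, 0.30, material="SPDP"),
            _protein("rspa", 69.0, 0.05, material="rSPA"),
        ),
        assumptions=("SPDP layer phi 0.30", "roughness values"),
    ),
    "rspa_bsa": ScenarioSpec(
        "rspa_bsa",
        "cross-linked rSPA after BSA blocking (protein phi up ~1.5 %)",
        layers=(
            _SIO2,
            _protein("spdp", 20.0, 0.30, material="SPDP"),
            _protein("rspa_bsa", 69.0, 0.065, material="rSPA"),
        ),
        assumptions=("SPDP layer phi 0.30", "roughness values"),
    ),
    "rspa_bsa_igg": ScenarioSpec(
        "rspa_bsa_igg",
        "IgG4 bound to rSPA/BSA surface: three IgG-related layers 61/52/67 Å",
        layers=(
            _SIO2,
            _protein("spdp", 20.0, 0.30, material="SPDP"),
            _protein("igg_inner", 61.0, 0.25),
            _protein("igg_middle", 52.0, 0.16),
            _protein("igg_outer", 67.0, 0.09),
        ),
        assumptions=("SPDP layer phi 0.30", "middle-layer phi 0.16", "roughness values"),
    ),
    "rspa_peg_igg": ScenarioSpec(
        "rspa_peg_igg",
        "IgG4 bound to rSPA/PEG surface: extended structure reaching ~230 Å",
        layers=(
            _SIO2,
            _protein("spdp_peg", 20.0, 0.35, material="SPDP"),
            _protein("igg_inner", 85.0, 0.22),
            _protein("igg_middle", 52.0, 0.14),
            _protein("igg_outer", 67.0, 0.09),
        ),
        assumptions=(
            "inner-layer thickness 85 Å (only the ~230-250 Å total extent is stated)",
            "phi values",
            "roughness values",
        ),
    ),
}


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; registered: {scenario_names()}"
        ) from None


def _layer_sld(layer: LayerSpec, solvent: SolventSpec, exchange: float) -> float:
    if layer.material is None:
        return layer.sld
    from .sld import material_sld

    rho_a = material_sld(material_preset(layer.material), solvent, exchange)
    return layer.phi * rho_a + (1.0 - layer.phi) * water_sld(solvent)


def build_scenario(
    name: str, contrasts: tuple[str, ...] | None = None
) -> dict[str, Stack]:
    """Per-contrast Stacks for a registered scenario.

    Protein-layer SLDs are recomputed for each solvent (labile-H exchange and
    solvation both depend on the D2O fraction); the backing medium is the
    solvent itself.
    """
    spec = get_scenario(name)
    stacks: dict[str, Stack] = {}
    for cname in contrasts or spec.contrasts:
        solvent = solvent_preset(cname)
        slabs = [
            Slab(
                thickness=l.thickness,
                sld=_layer_sld(l, solvent, spec.exchange_fraction),
                roughness=l.roughness,
                name=l.name,
            )
            for l in spec.layers
        ]
        stacks[cname] = Stack(
            fronting_sld=spec.fronting_sld,
            slabs=slabs,
            backing_sld=water_sld(solvent),
            backing_roughness=spec.backing_roughness,
        )
    return stacks


def default_q_grid(style: str = "ISIS", n_points: int = 120) -> np.ndarray:
    """Log-spaced Q grid typical of time-of-flight (ISIS-style) and
    monochromatic (NCNR-style) reflectometers."""
    ranges = {"ISIS": (0.01, 0.20), "NCNR": (0.008, 0.250)}
    try:
        lo, hi = ranges[style]
    except KeyError:
        raise KeyError(f"unknown grid style {style!r}; available: {sorted(ranges)}") from None
    return np.geomspace(lo, hi, n_points)


def simulate_experiment(
    stacks: dict[str, Stack],
    q_grid: np.ndarray,
    noise: NoiseModel = NoiseModel(),
) -> list[ContrastExperiment]:
    """Simulate one noisy, resolution-smeared curve per contrast.

    R_obs = smeared R_true + background + Gaussian noise with
    σ = max(relative_error_floor·R_true, background/3); the dR column is σ
    and the dQ column is the FWHM of the smearing kernel.  Negative draws are
    clipped at zero.  Deterministic for a given ``noise.seed``.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("empty q grid")
    rng = np.random.default_rng(noise.seed)
    experiments = []
    for cname, stack in stacks.items():
        r_true = smeared_reflectivity(stack, q, noise.dq_over_q).r
        sigma = np.maximum(
            noise.relative_error_floor * r_true, noise.background_level / 3.0
        )
        r_obs = r_true + noise.background_level + rng.normal(size=q.size) * sigma
        curve = ReflectivityCurve(
            q=q,
            r=np.clip(r_obs, 0.0, None),
            dr=sigma,
            dq=fwhm_dq(q, noise.dq_over_q) if noise.dq_over_q > 0 else None,
        )
        experiments.append(
            ContrastExperiment(
                curve=curve,
                solvent=solvent_preset(cname),
                background=FitParameter.fixed(
                    f"{cname}.background", noise.background_level
                ),
                name=cname,
            )
        )
    return experiments


def simulate_scenario(
    name: str,
    noise: NoiseModel = NoiseModel(),
    q_grid: np.ndarray | None = None,
    contrasts: tuple[str, ...] | None = None,
) -> list[ContrastExperiment]:
    """Convenience wrapper: build the scenario's stacks and simulate them."""
    stacks = build_scenario(name, contrasts)
    return simulate_experiment(
        stacks, default_q_grid() if q_grid is None else q_grid, noise
    )


def recovery_problem(
    name: str,
    experiments: list[ContrastExperiment],
    thickness_bounds: tuple[float, float] = (2.0, 150.0),
    phi_bounds: tuple[float, float] = (0.0, 0.8),
    vary_sio2: bool = True,
) -> tuple[FitProblem, dict[str, float]]:
    """A FitProblem for refitting a simulated scenario, plus the truth table.

    Protein-layer thicknesses and volume fractions vary inside generic
    bounds; roughnesses, the SiO2 SLD, scale and background stay fixed at
    the generating values (a known-instrument protocol).  The SiO2 thickness
    varies inside the usual [5, 20] Å native-oxide window when
    ``vary_sio2``.  Returns (problem, truth) where truth maps each free
    parameter name to its generating value.
    """
    spec = get_scenario(name)
    layers: list[LayerModel] = []
    truth: dict[str, float] = {}
    for l in spec.layers:
        if l.material is None:
            thick = FitParameter(
                f"{l.name}.thickness", l.thickness, (5.0, 20.0), vary=vary_sio2
            )
            layers.append(
                LayerModel(
                    name=l.name,
                    thickness=thick,
                    roughness=FitParameter.fixed(f"{l.name}.roughness", l.roughness),
                    sld=FitParameter.fixed(f"{l.name}.sld", l.sld),
                )
            )
            if vary_sio2:
                truth[thick.name] = l.thickness
        else:
            thick = FitParameter(
                f"{l.name}.thickness", l.thickness, thickness_bounds, vary=True
            )
            phi = FitParameter(f"{l.name}.phi", l.phi, phi_bounds, vary=True)
            layers.append(
                LayerModel(
                    name=l.name,
                    thickness=thick,
                    roughness=FitParameter.fixed(f"{l.name}.roughness", l.roughness),
                    material=material_preset(l.material),
                    phi=phi,
                    exchange_fraction=spec.exchange_fraction,
                )
            )
            truth[thick.name] = l.thickness
            truth[phi.name] = l.phi
    problem = FitProblem(
        layers=layers,
        contrasts=experiments,
        fronting_sld=spec.fronting_sld,
        backing_roughness=FitParameter.fixed(
            "backing_roughness", spec.backing_roughness
        ),
        dq_over_q=c.DEFAULT_DQ_OVER_Q,
    )
    return problem, truth
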