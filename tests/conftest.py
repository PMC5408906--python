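from __future__ import annotations

import numpy as np
import pytest

from slabrefl import (
    FitParameter,
    FitProblem,
    LayerModel,
    NoiseModel,
    Stack,
    material_preset,
    simulate_experiment,
    solvent_preset,
)
from slabrefl import constants as c
from slabrefl.slab import Slab


def random_stack(rng: np.random.Generator, max_slabs: int = 5) -> Stack:
    """A physically plausible random stack for oracle comparisons."""
    n = int(rng.integers(0, max_slabs + 1))
    slabs = [
        Slab(
            thickness=float(rng.uniform(0.0, 300.0)),
            sld=float(rng.uniform(-1e-6, 7e-6)),
            roughness=float(rng.uniform(0.0, 12.0)),
        )
        for _ in range(n)
    ]
    stack = Stack.__new__(Stack)
    stack.fronting_sld = float(rng.uniform(0.0, 3e-6))
    stack.slabs = slabs
    stack.backing_sld = float(rng.uniform(-0.6e-6, 6.4e-6))
    stack.backing_roughness = float(rng.uniform(0.0, 12.0))
    return stack


def stack_arrays(stack: Stack):
    """Stack fields in the layout the oracles expect."""
    return (
        stack.fronting_sld,
        [s.sld for s in stack.slabs],
        [s.thickness for s in stack.slabs],
        [s.roughness for s in stack.slabs] + [stack.backing_roughness],
        stack.backing_sld,
    )


def single_igg_layer_problem(
    seed: int = 0,
    contrasts: tuple[str, ...] = ("D2O", "H2O", "SMW"),
    n_points: int = 60,
    thickness: float = 31.0,
    phi: float = 0.40,
    noise: NoiseModel | None = None,
):
    """SiO2 + one IgG layer, simulated and wrapped as a FitProblem with the
    layer's thickness and phi free.  Returns (problem, truth dict)."""
    igg = material_preset("IgG4")
    noise = noise or NoiseModel(seed=seed)
    sio2 = Slab(10.0, c.SLD_SILICA, 3.0, name="sio2")
    stacks = {}
    for name in contrasts:
        solvent = solvent_preset(name)
        from slabrefl import material_sld, water_sld

        rho_a = material_sld(igg, solvent)
        rho_s = water_sld(solvent)
        layer = Slab(thickness, phi * rho_a + (1 - phi) * rho_s, 4.0, name="igg")
        stacks[name] = Stack(c.SLD_SILICON, [sio2, layer], rho_s, backing_roughness=4.0)
    q = np.geomspace(0.01, 0.20, n_points)
    experiments = simulate_experiment(stacks, q, noise)
    layers = [
        LayerModel(
            "sio2",
            thickness=FitParameter.fixed("sio2.thickness", 10.0),
            roughness=FitParameter.fixed("sio2.roughness", 3.0),
            sld=FitParameter.fixed("sio2.sld", c.SLD_SILICA),
        ),
        LayerModel(
            "igg",
            thickness=FitParameter("igg.thickness", thickness, (2.0, 150.0), vary=True),
            roughness=FitParameter.fixed("igg.roughness", 4.0),
            material=igg,
            phi=FitParameter("igg.phi", phi, (0.0, 0.8), vary=True),
        ),
    ]
    problem = FitProblem(
        layers,
        experiments,
        backing_roughness=FitParameter.fixed("backing_roughness", 4.0),
    )
    truth = {"igg.thickness": thickness, "igg.phi": phi}
    return problem, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
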