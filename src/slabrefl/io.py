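"""Plain-text reflectivity I/O and structured fit-problem configuration.

Reflectivity curves travel as whitespace- or comma-delimited columns
Q [Å⁻¹], R, dR, optional dQ (FWHM), with ``#`` comment headers — the
de-facto exchange format of reflectometry reduction software.  Fit problems,
scenarios and metric inputs are YAML.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import constants as c
from .sld import (
    MaterialComposition,
    SolventSpec,
    material_preset,
    solvent_preset,
)
from .slab import ReflectivityCurve, Stack, sld_profile
from .cofit import ContrastExperiment, FitParameter, FitProblem, LayerModel

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "write_sld_profile",
    "load_fit_problem",
    "config_hash",
]

DEFAULT_DR_FLOOR = 0.02  # synthesized relative dR for 2-column files


class ReflectivityParseError(ValueError):
    pass


def read_reflectivity(path: str | Path, dr_floor: float = DEFAULT_DR_FLOOR) -> ReflectivityCurve:
    """Read a 2/3/4-column text reflectivity file.

    Columns are Q, R[, dR[, dQ]]; ``#`` comments and blank lines are skipped.
    Files without a dR column get dR = ``dr_floor``·R (with a warning), so
    chi-squared remains defined.  Parse failures report the offending line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncols: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise ReflectivityParseError(
                    f"{path}:{lineno}: non-numeric value in {raw.strip()!r}"
                ) from None
            if len(values) < 2 or len(values) > 4:
                raise ReflectivityParseError(
                    f"{path}:{lineno}: expected 2-4 columns, got {len(values)}"
                )
            if any(np.isnan(v) for v in values):
                raise ReflectivityParseError(f"{path}:{lineno}: NaN value")
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ReflectivityParseError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(values)} vs {ncols})"
                )
            rows.append(values)
    if not rows:
        raise ReflectivityParseError(f"{path}: no data rows")
    data = np.asarray(rows)
    q = data[:, 0]
    bad = np.nonzero(np.diff(q) <= 0)[0]
    if bad.size:
        raise ReflectivityParseError(
            f"{path}: Q not strictly increasing at data row {bad[0] + 2}"
        )
    dr = data[:, 2] if ncols >= 3 else None
    if dr is None:
        warnings.warn(
            f"{path}: no dR column; synthesizing dR = {dr_floor:g}*R", stacklevel=2
        )
        dr = dr_floor * data[:, 1]
    return ReflectivityCurve(
        q=q, r=data[:, 1], dr=dr, dq=data[:, 3] if ncols == 4 else None
    )


def write_reflectivity(path: str | Path, curve: ReflectivityCurve, header: str = "") -> None:
    """Write a curve as Q/R[/dR[/dQ]] columns with a ``#`` header."""
    cols = [curve.q, curve.r]
    names = ["Q(1/Ang)", "R"]
    if curve.dr is not None:
        cols.append(curve.dr)
        names.append("dR")
        if curve.dq is not None:
            cols.append(curve.dq)
            names.append("dQ_FWHM(1/Ang)")
    head = (header.rstrip("\n") + "\n" if header else "") + " ".join(names)
    np.savetxt(Path(path), np.column_stack(cols), header=head, fmt="%.16e")


def write_sld_profile(
    path: str | Path, stack: Stack, z: np.ndarray | None = None
) -> np.ndarray:
    """Export the stack's SLD-vs-depth profile as two text columns (z, SLD)."""
    if z is None:
        extent = sum(s.thickness for s in stack.slabs)
        pad = 4 * max(
            [s.roughness for s in stack.slabs] + [stack.backing_roughness, 5.0]
        )
        z = np.linspace(-pad, extent + pad, 500)
    rho = sld_profile(stack, z)
    np.savetxt(Path(path), np.column_stack([z, rho]), header="z(Ang) SLD(1/Ang^2)")
    return rho


# ---------------------------------------------------------------------------
# Fit-problem configuration
# ---------------------------------------------------------------------------

def _parameter(name: str, node, default_vary: bool = False) -> FitParameter:
    if isinstance(node, (int, float)):
        return FitParameter(name, float(node))
    if not isinstance(node, dict) or "value" not in node:
        raise ValueError(f"parameter {name}: expected a number or a value/bounds/vary map")
    bounds = tuple(float(b) for b in node.get("bounds", (-np.inf, np.inf)))
    return FitParameter(
        name,
        float(node["value"]),
        bounds=bounds,
        vary=bool(node.get("vary", default_vary)),
        shared=bool(node.get("shared", True)),
    )


def _material_from_config(node, custom: dict[str, MaterialComposition]) -> MaterialComposition:
    if isinstance(node, str):
        return custom.get(node) or material_preset(node)
    return MaterialComposition(
        name=node["name"],
        b_total=float(node["b_total"]),
        molecular_volume=float(node["volume"]),
        n_labile_h=int(node.get("n_labile_h", 0)),
        mass_density=node.get("mass_density"),
    )


def _solvent_from_config(node) -> SolventSpec:
    if isinstance(node, str):
        return solvent_preset(node)
    return SolventSpec(float(node["d2o_volume_fraction"]), name=node.get("name", ""))


def load_fit_problem(
    source: str | Path | dict, data_dir: str | Path | None = None
) -> tuple[FitProblem, dict]:
    """Build a FitProblem from a YAML config file (or parsed mapping).

    Returns ``(problem, config)`` where ``config`` is the parsed mapping
    (carrying e.g. ``seed`` and optimizer settings for the caller).
    Layer blocks name either a material (preset or defined in a top-level
    ``materials:`` section) with a ``phi`` parameter, or a raw ``sld``
    parameter; contrast blocks name a data file and a solvent preset.
    """
    if isinstance(source, dict):
        cfg = source
        base = Path(data_dir) if data_dir else Path.cwd()
    else:
        source = Path(source)
        cfg = yaml.safe_load(source.read_text())
        base = Path(data_dir) if data_dir else source.parent

    custom = {
        name: _material_from_config({"name": name, **node}, {})
        for name, node in (cfg.get("materials") or {}).items()
    }

    layers = []
    for node in cfg.get("layers", []):
        name = node["name"]
        kwargs = dict(
            name=name,
            thickness=_parameter(f"{name}.thickness", node["thickness"]),
            roughness=_parameter(f"{name}.roughness", node.get("roughness", 0.0)),
        )
        if "material" in node:
            kwargs["material"] = _material_from_config(node["material"], custom)
            kwargs["phi"] = _parameter(f"{name}.phi", node["phi"])
            kwargs["exchange_fraction"] = float(
                node.get("exchange_fraction", c.DEFAULT_EXCHANGE_FRACTION)
            )
        else:
            kwargs["sld"] = _parameter(f"{name}.sld", node["sld"])
        layers.append(LayerModel(**kwargs))

    contrasts = []
    for node in cfg.get("contrasts", []):
        curve = read_reflectivity(base / node["file"])
        solvent = _solvent_from_config(node["solvent"])
        cname = node.get("name", solvent.name)
        contrasts.append(
            ContrastExperiment(
                curve=curve,
                solvent=solvent,
                scale=_parameter(f"{cname}.scale", node.get("scale", 1.0)),
                background=_parameter(f"{cname}.background", node.get("background", 0.0)),
                name=cname,
            )
        )

    problem = FitProblem(
        layers=layers,
        contrasts=contrasts,
        fronting_sld=float(cfg.get("fronting_sld", c.SLD_SILICON)),
        backing_roughness=_parameter(
            "backing_roughness", cfg.get("backing_roughness", 0.0)
        ),
        dq_over_q=float(cfg.get("dq_over_q", c.DEFAULT_DQ_OVER_Q)),
    )
    return problem, cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for run logs."""
    canon = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:12]
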