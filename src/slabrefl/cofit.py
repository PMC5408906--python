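"""Simultaneous multi-contrast refinement of a single layer depth profile.

One structural model (layer thicknesses, roughnesses, adsorbate volume
fractions) is shared across reflectivity curves measured in different
solvent contrasts; only the solvent SLD — and with it every solvated layer's
SLD, via ρ_l = φ·ρ_a(solvent) + (1−φ)·ρ_s(solvent) — changes between
contrasts.  Co-refining all contrasts against that one profile is what makes
sparse protein layers at a buried interface resolvable.

The fit statistic is a per-point-normalised chi-squared averaged over
contrasts (so curves with different point counts weigh equally); optimisation
is a seeded differential-evolution global search followed by a Nelder–Mead
polish; uncertainties come from a residual-resampling bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.signal import oaconvolve

from . import constants as c
from .sld import MaterialComposition, SolventSpec, material_sld, water_sld
from .slab import (
    ReflectivityCurve,
    Slab,
    Stack,
    _abeles_r,
    _gauss_kernel,
    _smear_ln_grid,
)

__all__ = [
    "FitParameter",
    "LayerModel",
    "ContrastExperiment",
    "FitProblem",
    "FitResult",
    "chi_squared",
    "fit",
    "bootstrap_errors",
    "compare_models",
]


@dataclass
class FitParameter:
    """A scalar model parameter with box bounds.

    ``shared=True`` (default) means one value across all contrasts — the
    normal case for structural parameters.  Per-contrast quantities (scale,
    background) are simply distinct FitParameter instances with
    ``shared=False``.
    """

    name: str
    value: float
    bounds: tuple[float, float] = (-math.inf, math.inf)
    vary: bool = False
    shared: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if lo > hi:
            raise ValueError(f"{self.name}: bounds low > high")
        if self.vary and not (lo <= self.value <= hi):
            raise ValueError(
                f"{self.name}: value {self.value} outside bounds {self.bounds}"
            )

    @classmethod
    def fixed(cls, name: str, value: float) -> "FitParameter":
        return cls(name, value, vary=False)


@dataclass
class LayerModel:
    """One slab of the shared structural model.

    Either ``material`` + ``phi`` (solvent-coupled SLD, recomputed per
    contrast) or a raw ``sld`` parameter (contrast-independent, for layers
    like SiO2 or the SPDP cross-linker when treated as unsolvated).
    """

    name: str
    thickness: FitParameter
    roughness: FitParameter
    material: MaterialComposition | None = None
    phi: FitParameter | None = None
    sld: FitParameter | None = None
    exchange_fraction: float = c.DEFAULT_EXCHANGE_FRACTION

    def __post_init__(self) -> None:
        if (self.material is None) == (self.sld is None):
            raise ValueError(f"layer {self.name}: give exactly one of material/sld")
        if self.material is not None and self.phi is None:
            raise ValueError(f"layer {self.name}: material layers need a phi parameter")

    def sld_in(self, solvent: SolventSpec) -> float:
        if self.material is None:
            return self.sld.value
        rho_a = material_sld(self.material, solvent, self.exchange_fraction)
        rho_s = water_sld(solvent)
        return self.phi.value * rho_a + (1.0 - self.phi.value) * rho_s

    def parameters(self) -> list[FitParameter]:
        params = [self.thickness, self.roughness]
        params.append(self.phi if self.material is not None else self.sld)
        return params


@dataclass
class ContrastExperiment:
    """One measured (or simulated) curve with its solvent, intensity scale
    and additive constant background."""

    curve: ReflectivityCurve
    solvent: SolventSpec
    scale: FitParameter | None = None
    background: FitParameter | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.solvent.name or f"x{self.solvent.d2o_volume_fraction:.2f}"
        if self.scale is None:
            self.scale = FitParameter.fixed(f"{self.name}.scale", 1.0)
        if self.background is None:
            self.background = FitParameter.fixed(f"{self.name}.background", 0.0)
        if self.scale.value <= 0:
            raise ValueError(f"{self.name}: scale must be > 0")
        if self.background.value < 0:
            raise ValueError(f"{self.name}: background must be >= 0")


class FitProblem:
    """A shared structural stack co-refined against ≥1 contrast curves.

    Parameters
    ----------
    layers : list of LayerModel, ordered silicon → solvent.
    contrasts : the experiments fitted simultaneously.
    fronting_sld : SLD of the incident medium (silicon wafer).
    backing_roughness : width of the last slab/solvent interface.
    dq_over_q : Gaussian resolution σ/Q used when a curve carries no dq
        column; curves with a dq column (FWHM) override it.
    """

    def __init__(
        self,
        layers: list[LayerModel],
        contrasts: list[ContrastExperiment],
        fronting_sld: float = c.SLD_SILICON,
        backing_roughness: FitParameter | None = None,
        dq_over_q: float = c.DEFAULT_DQ_OVER_Q,
    ) -> None:
        if not contrasts:
            raise ValueError("at least one contrast is required")
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        cnames = [x.name for x in contrasts]
        if len(set(cnames)) != len(cnames):
            raise ValueError("contrast names must be unique")
        self.layers = layers
        self.contrasts = contrasts
        self.fronting_sld = fronting_sld
        self.backing_roughness = backing_roughness or FitParameter.fixed(
            "backing_roughness", 0.0
        )
        self.dq_over_q = dq_over_q
        self._smear_cache: dict[int, tuple] = {}

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[FitParameter]:
        seen: dict[int, FitParameter] = {}
        for layer in self.layers:
            for p in layer.parameters():
                seen.setdefault(id(p), p)
        seen.setdefault(id(self.backing_roughness), self.backing_roughness)
        for x in self.contrasts:
            seen.setdefault(id(x.scale), x.scale)
            seen.setdefault(id(x.background), x.background)
        return list(seen.values())

    def free_parameters(self) -> list[FitParameter]:
        return [p for p in self.parameters() if p.vary]

    def free_values(self) -> np.ndarray:
        return np.array([p.value for p in self.free_parameters()])

    def set_free_values(self, x: np.ndarray) -> None:
        for p, v in zip(self.free_parameters(), x):
            p.value = float(v)

    # -- forward model ------------------------------------------------------

    def build_stack(self, solvent: SolventSpec) -> Stack:
        slabs = [
            Slab(
                thickness=l.thickness.value,
                sld=l.sld_in(solvent),
                roughness=l.roughness.value,
                name=l.name,
            )
            for l in self.layers
        ]
        stack = Stack.__new__(Stack)  # skip __post_init__ roughness warnings in hot path
        stack.fronting_sld = self.fronting_sld
        stack.slabs = slabs
        stack.backing_sld = water_sld(solvent)
        stack.backing_roughness = self.backing_roughness.value
        return stack

    def _smear_setup(self, contrast: ContrastExperiment):
        key = id(contrast)
        cached = self._smear_cache.get(key)
        if cached is None:
            q = contrast.curve.q
            if contrast.curve.dq is not None:
                # FWHM column → effective constant sigma/Q
                dqq = float(np.median(contrast.curve.dq / q)) / (
                    2.0 * math.sqrt(2.0 * math.log(2.0))
                )
            else:
                dqq = self.dq_over_q
            if dqq > 0:
                lnq_f, sigma_ln = _smear_ln_grid(q.min(), q.max(), dqq)
                kernel = _gauss_kernel(lnq_f[1] - lnq_f[0], sigma_ln)
                cached = (np.exp(lnq_f), lnq_f, kernel, np.log(q))
            else:
                cached = (q, None, None, None)
            self._smear_cache[key] = cached
        return cached

    def model_reflectivity(self, contrast: ContrastExperiment) -> np.ndarray:
        """Smeared model R on the contrast's Q grid (before scale/background)."""
        q_eval, lnq_f, kernel, lnq_data = self._smear_setup(contrast)
        stack = self.build_stack(contrast.solvent)
        slds, thick, rough = stack._arrays()
        r = _abeles_r(q_eval, slds, thick, rough)
        if kernel is None:
            return r
        return np.interp(lnq_data, lnq_f, np.convolve(r, kernel, mode="same"))

    def measured_model(self, contrast: ContrastExperiment) -> np.ndarray:
        """scale · R_model + background, comparable to the observed curve."""
        return (
            contrast.scale.value * self.model_reflectivity(contrast)
            + contrast.background.value
        )


@dataclass
class FitResult:
    params: dict[str, float]
    chi2_per_contrast: dict[str, float]
    chi2_total: float
    n_evaluations: int
    seed: int | None = None
    bootstrap: dict[str, tuple[float, float]] | None = None
    trace: list = field(default_factory=list)


def chi_squared(
    problem: FitProblem, x: np.ndarray | None = None
) -> tuple[dict[str, float], float]:
    """Per-contrast and total chi-squared.

    Per contrast: χ² = (1/N)·Σ((scale·R_model + bkg − R_obs)/dR)²; the total
    is the mean over contrasts, so each curve carries equal weight regardless
    of its point count.
    """
    if x is not None:
        problem.set_free_values(x)
    per: dict[str, float] = {}
    for contrast in problem.contrasts:
        dr = contrast.curve.dr
        if dr is None or np.any(dr <= 0):
            raise ValueError(
                f"contrast {contrast.name}: chi-squared needs dR > 0 everywhere; "
                "apply an uncertainty floor to the data first"
            )
        resid = (problem.measured_model(contrast) - contrast.curve.r) / dr
        per[contrast.name] = float(np.mean(resid**2))
    return per, float(np.mean(list(per.values())))


def _abeles_r_batch(q: np.ndarray, slds, thick, rough) -> np.ndarray:
    """|r|² for a population of stacks: slds/thick (M, S), rough (M-1, S),
    q (N,) → reflectivity (S, N).  Same optical-matrix arithmetic as the
    scalar path, broadcast over the population axis."""
    qsq4 = (q / 2.0) ** 2
    k = np.sqrt(
        qsq4[None, None, :] - 4.0 * np.pi * (slds[:, :, None] - slds[0][None, :, None]) + 0j
    )  # (M, S, N)
    r01 = (k[0] - k[1]) / (k[0] + k[1]) * np.exp(-2.0 * k[0] * k[1] * rough[0][:, None] ** 2)
    m00, m01 = np.ones_like(r01), r01.copy()
    m10, m11 = r01.copy(), np.ones_like(r01)
    # factored characteristic matrices; see the scalar implementation
    for i in range(1, slds.shape[0] - 1):
        rij = (k[i] - k[i + 1]) / (k[i] + k[i + 1]) * np.exp(
            -2.0 * k[i] * k[i + 1] * rough[i][:, None] ** 2
        )
        p = np.exp(-2j * k[i] * thick[i][:, None])
        rp = rij * p
        m00, m01, m10, m11 = (
            m00 + m01 * rp,
            m00 * rij + m01 * p,
            m10 + m11 * rp,
            m10 * rij + m11 * p,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.abs(m10 / m00) ** 2
    return np.clip(refl, 0.0, 1.0)


def chi_squared_batch(problem: FitProblem, x_pop: np.ndarray) -> np.ndarray:
    """Total chi-squared for a population of free-parameter vectors.

    ``x_pop`` has shape (n_free, S); returns (S,).  Numerically identical to
    evaluating :func:`chi_squared` column by column, but batches the optical
    matrices and the resolution convolution over the population, which is
    what makes a full-size differential-evolution population affordable.
    """
    x_pop = np.atleast_2d(np.asarray(x_pop, dtype=float))
    n_free, pop = x_pop.shape
    free = problem.free_parameters()
    index = {id(p): i for i, p in enumerate(free)}

    def values(p: FitParameter) -> np.ndarray:
        i = index.get(id(p))
        return x_pop[i] if i is not None else np.full(pop, p.value)

    totals = np.zeros(pop)
    for contrast in problem.contrasts:
        q_eval, lnq_f, kernel, lnq_data = problem._smear_setup(contrast)
        rho_s = water_sld(contrast.solvent)
        slds = [np.full(pop, problem.fronting_sld)]
        thick = [np.zeros(pop)]
        rough = []
        for layer in problem.layers:
            thick.append(values(layer.thickness))
            rough.append(values(layer.roughness))
            if layer.material is None:
                slds.append(values(layer.sld))
            else:
                rho_a = material_sld(
                    layer.material, contrast.solvent, layer.exchange_fraction
                )
                phi = values(layer.phi)
                slds.append(phi * rho_a + (1.0 - phi) * rho_s)
        slds.append(np.full(pop, rho_s))
        thick.append(np.zeros(pop))
        rough.append(values(problem.backing_roughness))
        r = _abeles_r_batch(q_eval, np.array(slds), np.array(thick), np.array(rough))
        if kernel is not None:
            r = oaconvolve(r, kernel[None, :], mode="same", axes=1)
            # linear interpolation onto the data grid (uniform ln-Q spacing)
            step = lnq_f[1] - lnq_f[0]
            pos = np.clip((lnq_data - lnq_f[0]) / step, 0.0, lnq_f.size - 1.000001)
            i0 = pos.astype(int)
            w = pos - i0
            r = r[:, i0] * (1.0 - w) + r[:, i0 + 1] * w
        model = values(contrast.scale)[:, None] * r + values(contrast.background)[:, None]
        resid = (model - contrast.curve.r[None, :]) / contrast.curve.dr[None, :]
        totals += np.mean(resid**2, axis=1)
    return totals / len(problem.contrasts)


def _check_free(problem: FitProblem) -> list[FitParameter]:
    free = problem.free_parameters()
    if not free:
        raise ValueError("no varying parameters")
    for p in free:
        if not (math.isfinite(p.bounds[0]) and math.isfinite(p.bounds[1])):
            raise ValueError(f"varying parameter {p.name} must have finite bounds")
    return free


def fit(
    problem: FitProblem,
    seed: int = 0,
    de_maxiter: int = 100,
    de_popsize: int = 15,
    de_tol: float = 0.005,
    polish: bool = True,
    global_search: bool = True,
    nm_maxiter: int = 4000,
    nm_xatol: float = 1e-8,
    restarts: int = 0,
    restart_chi2: float = 1.5,
) -> FitResult:
    """Seeded global fit: differential evolution then Nelder–Mead polish.

    ``de_popsize`` is per parameter (scipy convention); lowering
    ``de_maxiter``/``de_popsize`` trades confidence in the global optimum for
    speed.  ``global_search=False`` polishes from the current parameter
    values only (used for bootstrap refits).

    With ``restarts`` > 0 the global search is rerun from fresh, derived
    seeds while the best total chi-squared stays above ``restart_chi2`` —
    the usual guard against differential evolution settling in a secondary
    basin of a multimodal fringe landscape.  Deterministic for a given seed:
    restart seeds are derived from ``seed`` alone.
    """
    if restarts and global_search:
        best = None
        for attempt in range(restarts + 1):
            attempt_seed = (seed + 7919 * attempt) % (2**31 - 1)
            res = fit(
                problem,
                seed=attempt_seed,
                de_maxiter=de_maxiter,
                de_popsize=de_popsize,
                de_tol=de_tol,
                polish=polish,
                nm_maxiter=nm_maxiter,
                nm_xatol=nm_xatol,
            )
            if best is None or res.chi2_total < best.chi2_total:
                best = res
            if best.chi2_total <= restart_chi2:
                break
        free = problem.free_parameters()
        problem.set_free_values([best.params[p.name] for p in free])
        best.seed = seed
        return best
    free = _check_free(problem)
    bounds = [p.bounds for p in free]
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return chi_squared(problem, x)[1]

    def objective_batch(x: np.ndarray) -> np.ndarray | float:
        nonlocal n_eval
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            n_eval += 1
            return chi_squared_batch(problem, x[:, None])[0]
        n_eval += x.shape[1]
        return chi_squared_batch(problem, x)

    trace = []
    x0 = problem.free_values()
    if global_search:
        de = optimize.differential_evolution(
            objective_batch,
            bounds,
            seed=seed,
            maxiter=de_maxiter,
            popsize=de_popsize,
            tol=de_tol,
            polish=False,
            init="latinhypercube",
            updating="deferred",
            vectorized=True,
        )
        x0 = de.x
        trace.append(("differential_evolution", float(de.fun), int(de.nit)))
    if polish:
        nm = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": nm_xatol, "fatol": 1e-10, "maxiter": nm_maxiter},
        )
        if nm.fun <= objective(x0):
            x0 = nm.x
        trace.append(("nelder_mead", float(nm.fun), int(nm.nit)))
    problem.set_free_values(x0)
    per, total = chi_squared(problem)
    return FitResult(
        params={p.name: p.value for p in problem.parameters()},
        chi2_per_contrast=per,
        chi2_total=total,
        n_evaluations=n_eval,
        seed=seed,
        trace=trace,
    )


def bootstrap_errors(
    problem: FitProblem,
    best: FitResult,
    n_resamples: int = 100,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
    nm_maxiter: int = 600,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap intervals for the free parameters.

    Standardised residuals are resampled with replacement within each
    contrast (Q points are a fixed design, so cases are not resampled),
    pseudo-data are rebuilt around the best-fit model and re-polished from
    the best parameters.  Returns percentile intervals and attaches them to
    ``best.bootstrap``.  Deterministic for a given seed.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    free = _check_free(problem)
    best_x = np.array([best.params[p.name] for p in free])
    problem.set_free_values(best_x)
    models = [problem.measured_model(x) for x in problem.contrasts]
    resid = [
        (x.curve.r - m) / x.curve.dr for x, m in zip(problem.contrasts, models)
    ]
    originals = [x.curve for x in problem.contrasts]
    rng = np.random.default_rng(seed)
    samples = np.empty((n_resamples, len(free)))
    try:
        for b in range(n_resamples):
            for contrast, m, e, orig in zip(
                problem.contrasts, models, resid, originals
            ):
                idx = rng.integers(0, len(e), len(e))
                pseudo = np.clip(m + e[idx] * orig.dr, 0.0, None)
                contrast.curve = ReflectivityCurve(
                    q=orig.q, r=pseudo, dr=orig.dr, dq=orig.dq
                )
            problem._smear_cache.clear()
            problem.set_free_values(best_x)
            res = fit(
                problem,
                global_search=False,
                polish=True,
                nm_maxiter=nm_maxiter,
                nm_xatol=1e-6,
            )
            samples[b] = [res.params[p.name] for p in free]
    finally:
        for contrast, orig in zip(problem.contrasts, originals):
            contrast.curve = orig
        problem._smear_cache.clear()
        problem.set_free_values(best_x)
    lo, hi = np.percentile(samples, percentiles, axis=0)
    intervals = {p.name: (float(l), float(h)) for p, l, h in zip(free, lo, hi)}
    best.bootstrap = intervals
    return intervals


def compare_models(
    problems: dict[str, FitProblem],
    seed: int = 0,
    tie_threshold: float = 0.05,
    n_resamples: int = 0,
    **fit_kwargs,
) -> list[dict]:
    """Fit competing layer models to the same data and rank them.

    All problems must reference identical data (same contrasts, same
    curves).  Ranking is by total chi-squared; models within
    ``tie_threshold`` of the best are treated as tied and the tie is broken
    toward fewer layers (parsimony).  With ``n_resamples`` > 0 a bootstrap is
    run per model and the mean relative interval width of its free parameters
    is reported as a robustness diagnostic.
    """
    items = list(problems.items())
    ref = items[0][1]
    for label, prob in items[1:]:
        if len(prob.contrasts) != len(ref.contrasts):
            raise ValueError(f"model {label!r} is defined on different data")
        for a, b in zip(ref.contrasts, prob.contrasts):
            if not (
                np.array_equal(a.curve.q, b.curve.q)
                and np.array_equal(a.curve.r, b.curve.r)
            ):
                raise ValueError(f"model {label!r} is defined on different data")

    rows = []
    for label, prob in items:
        result = fit(prob, seed=seed, **fit_kwargs)
        row = {
            "label": label,
            "n_layers": len(prob.layers),
            "chi2_total": result.chi2_total,
            "result": result,
            "robustness": None,
        }
        if n_resamples > 0:
            intervals = bootstrap_errors(prob, result, n_resamples, seed=seed)
            widths = [
                abs(hi - lo) / max(abs(result.params[name]), 1e-30)
                for name, (lo, hi) in intervals.items()
            ]
            row["robustness"] = float(np.mean(widths))
        rows.append(row)

    rows.sort(key=lambda r: r["chi2_total"])
    best_chi2 = rows[0]["chi2_total"]
    tied = [r for r in rows if r["chi2_total"] - best_chi2 < tie_threshold]
    rest = [r for r in rows if r["chi2_total"] - best_chi2 >= tie_threshold]
    tied.sort(key=lambda r: (r["n_layers"], r["chi2_total"]))
    ranked = tied + rest
    for i, row in enumerate(ranked):
        row["rank"] = i + 1
    return ranked
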